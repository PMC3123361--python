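"""End-to-end pipeline: search -> superpose -> metal screen -> characterize.

Ties the stages together for one or more input structures and writes a
reproducible report bundle: per-hit table (hits.tsv), metal-site
characterization (sites.json), secondary-structure context (context.tsv)
and a summary row per structure (summary.json) with the position of the
first D, the extended-main-chain RMSD against the reference, the
additional-ligand separations and the bound metal.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .metal_analysis import build_site, detect_binuclear, link_site_to_motif
from .motif_search import (
    DEFAULT_PSEUDO_RMSD_CUTOFF,
    find_motifs,
    secondary_context,
)
from .structio import Structure, read_pdb
from .synthetic import reference_motif

logger = logging.getLogger(__name__)

HITS_COLUMNS = (
    "structure", "chain", "start", "motif_sequence", "pseudo_rmsd",
    "ext_rmsd_vs_ref", "metal", "context_up", "context_down",
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything one pipeline run depends on."""

    structures: list[str] = field(default_factory=list)
    output_dir: str = "camotif_out"
    pseudo_rmsd_cutoff: float = DEFAULT_PSEUDO_RMSD_CUTOFF
    coordination_cutoff: float = 3.0
    require_metal: bool = False
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self) -> None:
        if self.pseudo_rmsd_cutoff <= 0 or self.coordination_cutoff <= 0:
            raise ValueError("thresholds must be positive")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


def _analyse_structure(structure: Structure, config: RunConfig) -> dict:
    """All stages for one structure; returns rows for each output file."""
    reference = reference_motif()
    try:
        hits = find_motifs(
            structure,
            reference=reference,
            pseudo_rmsd_cutoff=config.pseudo_rmsd_cutoff,
            require_metal=config.require_metal,
            coordination_cutoff=config.coordination_cutoff,
        )
    except Exception as exc:
        raise PipelineError(f"motif-search stage failed on {structure.id}: {exc}")

    try:
        for hit in hits:
            secondary_context(hit, structure)
    except Exception as exc:
        raise PipelineError(f"context stage failed on {structure.id}: {exc}")

    try:
        sites = [
            build_site(structure, metal, cutoff=config.coordination_cutoff)
            for metal in structure.metals
        ]
        # link each motif hit to the site it ligates most closely
        for hit in hits:
            best, best_n = None, 0
            window_keys = {r.key() for r in hit.window_residues}
            for site in sites:
                n = sum(
                    1 for r in site.ligand_residues() if r.key() in window_keys
                )
                if n > best_n:
                    best, best_n = site, n
            if best is not None:
                link_site_to_motif(best, hit)
        pairs = detect_binuclear(sites) if len(sites) > 1 else []
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"metal stage failed on {structure.id}: {exc}")

    hit_rows = []
    for hit in hits:
        up, down = hit.context or ("other", "other")
        hit_rows.append(
            {
                "structure": structure.id,
                "chain": hit.chain_id,
                "start": hit.start,
                "motif_sequence": hit.motif_sequence,
                "pseudo_rmsd": f"{hit.pseudo_rmsd:.3f}",
                "ext_rmsd_vs_ref": (
                    "" if hit.ext_rmsd_vs_ref is None
                    else f"{hit.ext_rmsd_vs_ref:.2f}"
                ),
                "metal": "yes" if hit.metal_bound else "no",
                "context_up": up,
                "context_down": down,
            }
        )

    linked = [s for s in sites if s.linked_hit is not None]
    summary = {
        "structure": structure.id,
        "n_hits": len(hits),
        "first_d_positions": [h.start for h in hits],
        "ext_rmsd_vs_ref": [
            None if h.ext_rmsd_vs_ref is None else round(h.ext_rmsd_vs_ref, 2)
            for h in hits
        ],
        "metal_bound": [h.metal_bound for h in hits],
        "additional_separations": sorted(
            {sep for s in linked for sep in s.additional_separations}
        ),
        "n_metal_sites": len(sites),
        "n_binuclear_pairs": len(pairs),
        "metals": sorted({s.element for s in sites}),
    }
    return {
        "hits": hit_rows,
        "sites": [s.to_json_dict() for s in sites],
        "binuclear": [
            {
                "elements": [a.element, b.element],
                "shared_residues": [f"{r.res_name} {r.author_id}" for r in shared],
            }
            for a, b, shared in pairs
        ],
        "summary": summary,
    }


def run_pipeline(
    config: RunConfig, structures: list[Structure] | None = None
) -> dict:
    """Run all stages and write the report bundle under ``config.output_dir``.

    ``structures`` may be passed directly (e.g. synthetic ones); otherwise
    the paths in the config are read. Returns the summary dict. On any stage
    error, partial outputs are removed and a stage-named error is raised.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        if structures is None:
            try:
                structures = [read_pdb(p) for p in config.structures]
            except Exception as exc:
                raise PipelineError(f"input stage failed: {exc}")
        if not structures:
            raise PipelineError("input stage failed: no structures given")

        all_hits, all_sites, all_binuclear, summaries = [], [], [], []
        for structure in structures:
            result = _analyse_structure(structure, config)
            all_hits.extend(result["hits"])
            all_sites.append({"structure": structure.id, "sites": result["sites"]})
            all_binuclear.append(
                {"structure": structure.id, "pairs": result["binuclear"]}
            )
            summaries.append(result["summary"])

        hits_path = out / "hits.tsv"
        with hits_path.open("w") as fh:
            fh.write("\t".join(HITS_COLUMNS) + "\n")
            for row in all_hits:
                fh.write("\t".join(str(row[c]) for c in HITS_COLUMNS) + "\n")
        written.append(hits_path)

        sites_path = out / "sites.json"
        sites_path.write_text(
            json.dumps(
                {"schema_version": 1, "structures": all_sites,
                 "binuclear": all_binuclear},
                indent=2, sort_keys=True,
            )
            + "\n"
        )
        written.append(sites_path)

        context_path = out / "context.tsv"
        with context_path.open("w") as fh:
            fh.write("structure\tchain\tstart\tcontext_up\tcontext_down\n")
            for row in all_hits:
                fh.write(
                    f"{row['structure']}\t{row['chain']}\t{row['start']}\t"
                    f"{row['context_up']}\t{row['context_down']}\n"
                )
        written.append(context_path)

        summary_path = out / "summary.json"
        summary_path.write_text(
            json.dumps(
                {
                    "tool": "camotif",
                    "version": __version__,
                    "config_hash": config.digest(),
                    "seed": config.seed,
                    "structures": summaries,
                },
                indent=2, sort_keys=True,
            )
            + "\n"
        )
        written.append(summary_path)
        logger.info(
            "pipeline complete: %d structure(s), %d hit(s); config %s seed %d",
            len(structures), len(all_hits), config.digest(), config.seed,
        )
        return {"summaries": summaries, "outputs": [str(p) for p in written]}
    except PipelineError:
        for path in written:
            path.unlink(missing_ok=True)
        raise
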