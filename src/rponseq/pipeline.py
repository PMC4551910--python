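"""End-to-end pipeline: simulate → quantify → contrast → scan → classify.

Runs every stage under one configuration, writes all stage outputs in
standard formats plus a YAML run manifest (configuration hash, seeds,
per-stage file list with content digests).  The whole pipeline is
deterministic: identical configurations produce byte-identical outputs and
an identical manifest hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .contrast import (
    DEFAULT_ALPHA,
    DEFAULT_T_BYPASS,
    DEFAULT_T_MAJOR,
    call_genome,
)
from .motifs import MODELS, PromoterSite, scan
from .quantify import CONTRASTS, DEFAULT_PSEUDOCOUNT, ExpressionTable, build_expression_table
from .siteclass import (
    DEFAULT_DISTAL_CUTOFF,
    DEFAULT_PAD_DOWNSTREAM,
    DEFAULT_PAD_UPSTREAM,
    classify_repressed_set,
)
from .synthetic import (
    SimParams,
    _params_from_dict,
    _params_to_dict,
    build_genome,
    simulate_counts,
    write_fixture,
)

logger = logging.getLogger("rponseq.pipeline")

FOUR_FOLD_BOUNDARY = 2.0  # |M| boundary of the MA-plot shaded region


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


@dataclass
class PipelineConfig:
    """Complete configuration of one pipeline run.

    ``seed`` drives genome construction; counts use ``seed + 1`` so the
    genome is reusable across count replicates.  All thresholds mirror the
    per-module defaults and round-trip losslessly through YAML.
    """

    seed: int = 42
    n_genes: int = 500
    n_planted_per_type: dict = field(
        default_factory=lambda: {
            "sigma54_activator_dependent": 10,
            "sigma54_bypass": 10,
            "sigma70_constitutive": 10,
            "sigma70_repressed_by_sigma54": 10,
        }
    )
    depth: int = 2_000_000
    n_replicates: int = 3
    dispersion: float = 10.0
    sim: SimParams = field(default_factory=SimParams)
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    t_major: float = DEFAULT_T_MAJOR
    t_bypass: float = DEFAULT_T_BYPASS
    alpha: float = DEFAULT_ALPHA
    sigma54_threshold: float = 2.0
    sigma70_threshold: float = 3.0
    window_upstream: int = 300
    window_downstream: int = 100
    pad_upstream: int = DEFAULT_PAD_UPSTREAM
    pad_downstream: int = DEFAULT_PAD_DOWNSTREAM
    distal_cutoff: int = DEFAULT_DISTAL_CUTOFF
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("pseudocount", "t_major", "t_bypass", "alpha",
                     "sigma54_threshold", "sigma70_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = _params_to_dict(self.sim)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sim" in d and not isinstance(d["sim"], SimParams):
            d["sim"] = _params_from_dict(d["sim"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        io.write_yaml(path, self.to_dict())

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(io.read_yaml(path))

    @property
    def config_hash(self) -> str:
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()


def configure_logging(level: str = "INFO") -> None:
    """Stage-tagged logging to stderr."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(name)s] %(levelname)s %(message)s"))
    root = logging.getLogger("rponseq")
    root.handlers[:] = [handler]
    root.setLevel(level.upper())


# ---------------------------------------------------------------------------
# site (de)serialisation
# ---------------------------------------------------------------------------

SITE_COLUMNS = [
    "seq_id", "motif_id", "strand", "start", "end",
    "up_name", "up_start", "up_end", "up_seq",
    "down_name", "down_start", "down_end", "down_seq",
    "spacer", "mismatches", "score", "tss", "minus12_base",
]


def site_table(sites: list[PromoterSite]) -> pd.DataFrame:
    rows = []
    for s in sites:
        (un, us, ue), (dn, ds, de) = s.elements
        rows.append(
            [s.seq_id, s.motif_id, s.strand, s.start, s.end,
             un, us, ue, s.matched_seq(un),
             dn, ds, de, s.matched_seq(dn),
             s.spacer, s.mismatches, s.score, s.tss,
             s.minus12_base if s.minus12_base is not None else ""]
        )
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


def sites_from_table(df: pd.DataFrame) -> list[PromoterSite]:
    sites = []
    for row in df.itertuples(index=False):
        minus12 = row.minus12_base if isinstance(row.minus12_base, str) and row.minus12_base else None
        sites.append(
            PromoterSite(
                motif_id=row.motif_id,
                strand=row.strand,
                start=int(row.start),
                end=int(row.end),
                elements=(
                    (row.up_name, int(row.up_start), int(row.up_end)),
                    (row.down_name, int(row.down_start), int(row.down_end)),
                ),
                matched=((row.up_name, row.up_seq), (row.down_name, row.down_seq)),
                spacer=int(row.spacer),
                mismatches=float(row.mismatches),
                score=float(row.score),
                tss=int(row.tss),
                minus12_base=minus12,
                seq_id=row.seq_id,
            )
        )
    return sites


def sites_to_bed(sites: list[PromoterSite], model_total_weight: float) -> list[tuple]:
    """BED6 records with the similarity score rescaled to 0–1000."""
    records = []
    for s in sites:
        scaled = int(round(1000 * s.score / model_total_weight))
        records.append((s.seq_id, s.start, s.end, s.motif_id, scaled, s.strand))
    return records


def export_ma_plot_data(
    expr: ExpressionTable,
    contrast: str,
    boundary: float = FOUR_FOLD_BOUNDARY,
) -> pd.DataFrame:
    """Per-gene (A, M, four_fold_flag) for one contrast.

    ``four_fold_flag`` is true when |M| strictly exceeds the boundary:
    genes at most four-fold differently expressed (|M| ≤ 2) sit inside the
    MA-plot shaded region and are not flagged.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; expected one of {sorted(CONTRASTS)}")
    df = pd.DataFrame(
        {
            "gene_id": expr.summary.index,
            "A": expr.a(contrast).to_numpy(),
            "M": expr.m(contrast).to_numpy(),
        }
    )
    df["four_fold_flag"] = np.abs(df["M"]) > boundary
    return df


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: PipelineConfig, outdir) -> dict:
    """Execute the full pipeline; returns the run manifest."""
    out = io.ensure_dir(outdir)
    stage_files: dict[str, list[str]] = {}
    summaries: dict[str, dict] = {}

    def run_stage(name, fn, *inputs):
        logger.info("stage %s", name)
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            detail = f" (input: {inputs[0]})" if inputs else ""
            raise PipelineError(f"stage {name} failed{detail}: {exc}") from exc

    # simulate
    def _simulate():
        genome = build_genome(
            config.n_genes, config.n_planted_per_type, config.seed, config.sim
        )
        counts = simulate_counts(
            genome, config.depth, config.n_replicates, config.dispersion,
            seed=config.seed + 1,
        )
        write_fixture(genome, counts, out)
        return genome, counts

    genome, counts = run_stage("simulate", _simulate)
    stage_files["simulate"] = ["genome.fa", "genes.gff3", "truth.bed",
                               "counts.tsv", "manifest.yaml"]

    # quantify
    def _quantify():
        lengths = {g.gene_id: g.length_bp for g in genome.genes}
        expr = build_expression_table(counts, lengths, config.pseudocount)
        expr.to_tsv(out / "expression.tsv")
        return expr

    expr = run_stage("quantify", _quantify, "counts.tsv")
    stage_files["quantify"] = ["expression.tsv"]

    # contrast
    def _contrast():
        calls, summary = call_genome(
            expr, config.t_major, config.t_bypass, config.alpha
        )
        calls.reset_index().to_csv(out / "calls.tsv", sep="\t", index=False)
        io.write_yaml(out / "call_summary.yaml", summary.to_dict())
        return calls, summary

    calls, call_summary = run_stage("contrast", _contrast, "expression.tsv")
    stage_files["contrast"] = ["calls.tsv", "call_summary.yaml"]
    summaries["contrast"] = {k: int(v) for k, v in call_summary.items()}

    # scan
    def _scan():
        found = {}
        for motif_id, threshold in (
            ("sigma54", config.sigma54_threshold),
            ("sigma70", config.sigma70_threshold),
        ):
            sites = scan(genome.sequence, MODELS[motif_id], threshold=threshold)
            found[motif_id] = sites
            io.write_tsv(out / f"sites_{motif_id}.tsv", site_table(sites))
            io.write_bed(
                out / f"sites_{motif_id}.bed",
                sites_to_bed(sites, MODELS[motif_id].total_weight),
            )
        return found

    sites = run_stage("scan", _scan, "genome.fa")
    stage_files["scan"] = [
        "sites_sigma54.tsv", "sites_sigma54.bed",
        "sites_sigma70.tsv", "sites_sigma70.bed",
    ]
    summaries["scan"] = {m: len(s) for m, s in sites.items()}

    # classify repressed sites
    def _classify():
        return classify_repressed_set(
            calls, sites["sigma54"], sites["sigma70"], genome.genes,
            window_upstream=config.window_upstream,
            window_downstream=config.window_downstream,
            pad_upstream=config.pad_upstream,
            pad_downstream=config.pad_downstream,
            distal_cutoff=config.distal_cutoff,
        )

    classification = run_stage("classify_sites", _classify, "calls.tsv")
    io.write_tsv(out / "site_classes.tsv", classification.to_frame())
    class_bed = [
        ("genome", c.sigma54_site.start, c.sigma54_site.end,
         f"class_{c.site_class}", 0, c.sigma54_site.strand)
        for c in classification.calls
    ]
    io.write_bed(out / "site_classes.bed", class_bed)
    io.write_yaml(
        out / "site_class_summary.yaml",
        {
            "counts": classification.counts,
            "consensus": classification.consensus,
            "unclassifiable": [list(u) for u in classification.unclassifiable],
            "thresholds": {
                "pad_upstream": config.pad_upstream,
                "pad_downstream": config.pad_downstream,
                "distal_cutoff": config.distal_cutoff,
            },
        },
    )
    stage_files["classify_sites"] = [
        "site_classes.tsv", "site_classes.bed", "site_class_summary.yaml"
    ]
    summaries["classify_sites"] = dict(classification.counts)

    # report: MA plot data per contrast
    def _report():
        for name in CONTRASTS:
            io.write_tsv(out / f"ma_{name}.tsv", export_ma_plot_data(expr, name))

    run_stage("report", _report, "expression.tsv")
    stage_files["report"] = [f"ma_{name}.tsv" for name in CONTRASTS]

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash,
        "version": __version__,
        "seeds": {"genome": config.seed, "counts": config.seed + 1},
        "stages": {
            name: {"files": {f: _sha256(out / f) for f in files}}
            for name, files in stage_files.items()
        },
        "summaries": summaries,
    }
    manifest_yaml = yaml.safe_dump(manifest, sort_keys=True)
    manifest["manifest_hash"] = hashlib.sha256(manifest_yaml.encode()).hexdigest()
    io.write_yaml(out / "run_manifest.yaml", manifest)
    return manifest
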