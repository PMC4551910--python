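"""Synthetic genomes with planted promoters and three-strain RNA-seq counts.

The generator emulates the measurement setting of a genome-wide comparison
of three otherwise isogenic E. coli strains: ``WT`` (wild-type σ54), ``dRI``
(σ54 lacking the repressive Region I, the activator-bypass allele) and
``none`` (no σ54).  A random genome segment carries annotated genes, and a
chosen subset of genes is driven by planted promoters of four functional
types:

* ``sigma54_activator_dependent`` — canonical −24/−12 promoter, active only
  with wild-type σ54 and its activator (multipliers WT:dRI:none = 8:1:1);
* ``sigma54_bypass`` — −24/−12 promoter with a non-consensus −12 base that
  permits low-level activator-independent transcription by the ΔRI form
  (8:2.5:1);
* ``sigma70_constitutive`` — −35/−10 promoter, strain-independent (1:1:1);
* ``sigma70_repressed_by_sigma54`` — an active −35/−10 promoter plus a σ54
  site placed in one of four positional configurations (classes I–IV)
  relative to it; expression rises when σ54 is absent (1:1:8).

All consensus elements are written verbatim into the sequence at fixed
strand-aware offsets from the planted tss, and the background is scrubbed
of spurious perfect consensus cores, so the truth table is exhaustive and
every planted site is rediscoverable by the scanner.  Read counts are drawn
from a negative binomial with mean proportional to gene length and strain
activity and variance μ + μ²/k (shared dispersion k).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import io
from .motifs import (
    SIGMA54,
    SIGMA70,
    decode_sequence,
    encode_sequence,
    revcomp,
    scan,
)

STRAINS = ("WT", "dRI", "none")

PROMOTER_TYPES = (
    "sigma54_activator_dependent",
    "sigma54_bypass",
    "sigma70_constitutive",
    "sigma70_repressed_by_sigma54",
)

SITE_CLASSES = ("I", "II", "III", "IV")

#: Default per-strain expression multipliers for each promoter type.
DEFAULT_ACTIVITIES = {
    "sigma54_activator_dependent": {"WT": 8.0, "dRI": 1.0, "none": 1.0},
    "sigma54_bypass": {"WT": 8.0, "dRI": 2.5, "none": 1.0},
    "sigma70_constitutive": {"WT": 1.0, "dRI": 1.0, "none": 1.0},
    "sigma70_repressed_by_sigma54": {"WT": 1.0, "dRI": 1.0, "none": 8.0},
}


@dataclass(frozen=True)
class SimParams:
    """Genome-construction parameters.

    Gene lengths and intergenic gaps are drawn uniformly from the given
    inclusive ranges; the minimum gap leaves room for the widest planted
    promoter layout on both sides of a shared gap.  ``promoter_offset`` is
    the distance from a planted tss to its gene's 5' end.
    ``repressed_classes`` is cycled over planted repressed promoters.
    """

    gene_length_range: tuple[int, int] = (300, 1500)
    intergenic_range: tuple[int, int] = (220, 400)
    gc: float = 0.5
    promoter_offset: int = 25
    repressed_classes: tuple[str, ...] = SITE_CLASSES
    bypass_minus12_base: str = "A"
    activities: dict = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_ACTIVITIES)
    )
    both_strands: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.gc < 1.0:
            raise ValueError("gc must be in (0, 1)")
        if self.gene_length_range[0] < 300:
            raise ValueError("minimum gene length must be ≥ 300 (class IV sites sit in the gene body)")
        if self.intergenic_range[0] < 220:
            raise ValueError("minimum intergenic gap must be ≥ 220 to host two promoter layouts")
        bad = set(self.repressed_classes) - set(SITE_CLASSES)
        if bad:
            raise ValueError(f"unknown site classes {sorted(bad)}")
        if self.bypass_minus12_base == "C":
            raise ValueError("bypass promoters carry a non-consensus −12 base")


@dataclass(frozen=True)
class Gene:
    gene_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must precede end")
        if self.length_bp < 50:
            raise ValueError(f"{self.gene_id}: genes must be ≥ 50 bp")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class PlantedPromoter:
    """Ground-truth record of one planted promoter configuration.

    ``elements`` maps element names to forward-strand half-open intervals;
    repressed configurations additionally carry the σ54 site geometry under
    ``s54_minus24`` / ``s54_minus12`` with its own strand, tss and class.
    """

    promoter_type: str
    tss: int
    strand: str
    target_gene_id: str
    activity: dict[str, float]
    minus12_base: str | None = None
    elements: dict[str, tuple[int, int]] = field(default_factory=dict)
    site_class: str | None = None
    sigma54_strand: str | None = None
    sigma54_tss: int | None = None


@dataclass
class GenomeModel:
    sequence: str
    genes: list[Gene]
    promoters: list[PlantedPromoter]
    seed: int
    params: SimParams

    def validate(self) -> None:
        L = len(self.sequence)
        for g in self.genes:
            if not (0 <= g.start < g.end <= L):
                raise ValueError(f"{g.gene_id} outside sequence")
        for strand in "+-":
            prev_end = -1
            for g in sorted(
                (g for g in self.genes if g.strand == strand), key=lambda g: g.start
            ):
                if g.start < prev_end:
                    raise ValueError(f"{g.gene_id} overlaps a same-strand gene")
                prev_end = g.end
        for p in self.promoters:
            for name, (s, e) in p.elements.items():
                if not (0 <= s < e <= L):
                    raise ValueError(
                        f"{p.target_gene_id} element {name} outside sequence"
                    )

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


@dataclass
class CountMatrix:
    """Genes × (strain, replicate) integer read counts.

    ``counts`` is indexed by gene_id with flat columns ``WT_1 … none_R``;
    library sizes are exact column sums.
    """

    counts: pd.DataFrame
    strains: tuple[str, ...] = STRAINS
    n_replicates: int = 3

    def columns_for(self, strain: str) -> list[str]:
        return [f"{strain}_{r}" for r in range(1, self.n_replicates + 1)]

    def library_size(self, strain: str, replicate: int) -> int:
        return int(self.counts[f"{strain}_{replicate}"].sum())

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

def _frame_pos(tss: int, strand: str, offset: int) -> int:
    """Forward coordinate of a strand-frame offset from tss (downstream > 0)."""
    return tss + offset if strand == "+" else tss - offset


def _frame_interval(tss: int, strand: str, a: int, b: int) -> tuple[int, int]:
    """Forward half-open interval of strand-frame [a, b) relative to tss."""
    if strand == "+":
        return tss + a, tss + b
    return tss - b + 1, tss - a + 1


def _sigma54_plan(minus12_base: str) -> list[tuple[str, int, int, str]]:
    # −24 element at [−26, −19), spacer 4, −12 element at [−15, −10);
    # the C consensus position lands exactly at −12 so the scanner's tss
    # inference (C position + 12) recovers the planted tss.
    return [
        ("minus24", -26, -19, "TGGCACG"),
        ("minus12", -15, -10, "TTG" + minus12_base + "T"),
    ]


def _sigma70_plan() -> list[tuple[str, int, int, str]]:
    # −10 start at −7 so the scanner's tss inference (−10 start + 7)
    # recovers the planted tss; 17 nt spacer to the −35 element.
    return [
        ("minus35", -30, -24, "TTGACA"),
        ("minus10", -7, -1, "TATAAT"),
    ]


def _repressed_sigma54_geometry(gene_strand: str, site_class: str) -> tuple[str, int]:
    """(σ54 strand, strand-frame tss offset from the σ70 tss) per class.

    Offsets are chosen so that, with default footprint pads (5, 20) and a
    100 bp distal cutoff: class I overlaps the σ70 footprint on the same
    strand without touching the −35/−10 elements themselves; class II is
    the same overlap on the opposite strand; class III sits 30 bp upstream
    of the footprint; class IV lies on the opposite strand 130 bp
    downstream of the σ70 tss (110 bp beyond the footprint).
    """
    opposite = "-" if gene_strand == "+" else "+"
    geometries = {
        "I": (gene_strand, 2),
        "II": (opposite, -35),
        "III": (gene_strand, -55),
        "IV": (opposite, 119),
    }
    return geometries[site_class]


def _plant(
    seq: np.ndarray,
    claimed: np.ndarray,
    tss: int,
    strand: str,
    plan: list[tuple[str, int, int, str]],
    prefix: str = "",
) -> dict[str, tuple[int, int]]:
    elements: dict[str, tuple[int, int]] = {}
    for name, a, b, content in plan:
        i0, i1 = _frame_interval(tss, strand, a, b)
        if i0 < 0 or i1 > len(seq):
            raise ValueError(f"planted element {name} runs off the sequence")
        if claimed[i0:i1].any():
            raise ValueError(
                f"planted element {name} at [{i0}, {i1}) overlaps another planted element"
            )
        oriented = content if strand == "+" else revcomp(content)
        seq[i0:i1] = encode_sequence(oriented)
        claimed[i0:i1] = True
        elements[prefix + name] = (i0, i1)
    return elements


def _scrub_spurious(seq: np.ndarray, claimed: np.ndarray, rng, probs) -> None:
    """Resample background windows that contain a perfect consensus core.

    Keeps the truth table exhaustive: after scrubbing, the only
    zero-mismatch σ54/σ70 sites in the genome are planted ones.
    """
    for _ in range(50):
        dirty = False
        text = decode_sequence(seq)
        for model in (SIGMA54, SIGMA70):
            for site in scan(text, model, threshold=0.0):
                positions = np.concatenate(
                    [np.arange(s, e) for _, s, e in site.elements]
                )
                free = positions[~claimed[positions]]
                if free.size == 0:
                    continue  # fully planted: a genuine truth site
                seq[free] = rng.choice(4, size=free.size, p=probs)
                dirty = True
        if not dirty:
            return
    raise RuntimeError("could not scrub spurious consensus sites in 50 rounds")


def build_genome(
    n_genes: int,
    n_planted_per_type: dict[str, int],
    seed: int,
    params: SimParams | None = None,
) -> GenomeModel:
    """Generate a genome with annotated genes and planted promoters.

    Each planted σ54 promoter has its −24/−12 elements written verbatim at
    fixed offsets from its tss (strand-aware), each σ70 promoter its
    −35/−10 elements, and repressed configurations additionally a σ54 site
    in the requested positional class.  Identical (params, seed) give a
    byte-identical genome.
    """
    params = params or SimParams()
    bad = set(n_planted_per_type) - set(PROMOTER_TYPES)
    if bad:
        raise ValueError(f"unknown promoter types {sorted(bad)}")
    if any(v < 0 for v in n_planted_per_type.values()):
        raise ValueError("planted counts must be non-negative")
    total_planted = sum(n_planted_per_type.values())
    if total_planted and n_genes < 4 * total_planted:
        raise ValueError(
            f"need n_genes ≥ 4 × planted promoters ({4 * total_planted}), got {n_genes}"
        )
    if n_genes < 1:
        raise ValueError("n_genes must be ≥ 1")

    rng = np.random.default_rng(seed)
    glo, ghi = params.gene_length_range
    ilo, ihi = params.intergenic_range
    lengths = rng.integers(glo, ghi + 1, size=n_genes)
    gaps = rng.integers(ilo, ihi + 1, size=n_genes + 1)
    if params.both_strands:
        strands = np.where(rng.random(n_genes) < 0.5, "+", "-")
    else:
        strands = np.full(n_genes, "+")

    starts = np.zeros(n_genes, dtype=int)
    pos = int(gaps[0])
    genes: list[Gene] = []
    width = len(str(n_genes))
    for i in range(n_genes):
        starts[i] = pos
        genes.append(
            Gene(f"g{i + 1:0{width}d}", pos, pos + int(lengths[i]), str(strands[i]))
        )
        pos += int(lengths[i]) + int(gaps[i + 1])
    L = pos

    gc = params.gc
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = rng.choice(4, size=L, p=probs).astype(np.uint8)
    claimed = np.zeros(L, dtype=bool)

    order = rng.permutation(n_genes)
    promoters: list[PlantedPromoter] = []
    cursor = 0
    for ptype in PROMOTER_TYPES:
        n_repressed_seen = 0
        for _ in range(n_planted_per_type.get(ptype, 0)):
            g = genes[order[cursor]]
            cursor += 1
            activity = dict(params.activities[ptype])
            tss = _frame_pos(g.five_prime, g.strand, -params.promoter_offset)
            if ptype in ("sigma54_activator_dependent", "sigma54_bypass"):
                base = "C" if ptype == "sigma54_activator_dependent" else params.bypass_minus12_base
                elements = _plant(seq, claimed, tss, g.strand, _sigma54_plan(base))
                promoters.append(
                    PlantedPromoter(ptype, tss, g.strand, g.gene_id, activity,
                                    minus12_base=base, elements=elements)
                )
            elif ptype == "sigma70_constitutive":
                elements = _plant(seq, claimed, tss, g.strand, _sigma70_plan())
                promoters.append(
                    PlantedPromoter(ptype, tss, g.strand, g.gene_id, activity,
                                    elements=elements)
                )
            else:  # sigma70_repressed_by_sigma54
                cls = params.repressed_classes[
                    n_repressed_seen % len(params.repressed_classes)
                ]
                n_repressed_seen += 1
                elements = _plant(seq, claimed, tss, g.strand, _sigma70_plan())
                s54_strand, offset = _repressed_sigma54_geometry(g.strand, cls)
                s54_tss = _frame_pos(tss, g.strand, offset)
                elements.update(
                    _plant(seq, claimed, s54_tss, s54_strand, _sigma54_plan("C"),
                           prefix="s54_")
                )
                promoters.append(
                    PlantedPromoter(ptype, tss, g.strand, g.gene_id, activity,
                                    minus12_base="C", elements=elements,
                                    site_class=cls, sigma54_strand=s54_strand,
                                    sigma54_tss=s54_tss)
                )

    _scrub_spurious(seq, claimed, rng, probs)
    model = GenomeModel(decode_sequence(seq), genes, promoters, seed, params)
    model.validate()
    return model


# ---------------------------------------------------------------------------
# count simulation
# ---------------------------------------------------------------------------

def activity_matrix(genome: GenomeModel) -> pd.DataFrame:
    """Per-gene, per-strain expression multipliers from the truth table."""
    acts = pd.DataFrame(
        1.0, index=[g.gene_id for g in genome.genes], columns=list(STRAINS)
    )
    for p in genome.promoters:
        for strain in STRAINS:
            acts.loc[p.target_gene_id, strain] = p.activity[strain]
    return acts


def expected_means(genome: GenomeModel, depth: int) -> pd.DataFrame:
    """Expected read counts μ(gene, strain).

    μ = depth × (length/1000) × activity / normaliser.  The normaliser is
    shared across strains (the strain-averaged Σ length_kb × activity) so
    that cross-strain mean ratios equal the planted activity ratios
    exactly; per-strain expected totals then deviate from ``depth`` only by
    the strain's share of planted differential genes (within 10% under the
    default design, where planted genes are a small minority).
    """
    acts = activity_matrix(genome)
    len_kb = pd.Series(
        {g.gene_id: g.length_bp / 1000.0 for g in genome.genes}
    ).reindex(acts.index)
    weighted = acts.mul(len_kb, axis=0)
    return depth * weighted / weighted.sum(axis=0).mean()


def simulate_counts(
    genome: GenomeModel,
    depth: int,
    n_replicates: int = 3,
    dispersion: float = 10.0,
    seed: int = 0,
) -> CountMatrix:
    """Draw negative-binomial read counts for the three strains.

    Counts are NB with mean μ(gene, strain) from :func:`expected_means` and
    variance μ + μ²/dispersion (shared dispersion).  Identical arguments
    give identical counts.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    mu = expected_means(genome, depth)
    rng = np.random.default_rng(seed)
    k = float(dispersion)
    data = {}
    for strain in STRAINS:
        m = mu[strain].to_numpy()
        p = k / (k + m)
        for rep in range(1, n_replicates + 1):
            data[f"{strain}_{rep}"] = rng.negative_binomial(k, p)
    df = pd.DataFrame(data, index=mu.index)
    df.index.name = "gene_id"
    return CountMatrix(df, STRAINS, n_replicates)


# ---------------------------------------------------------------------------
# fixture round trip
# ---------------------------------------------------------------------------

def _promoter_to_dict(p: PlantedPromoter) -> dict:
    d = asdict(p)
    d["elements"] = {k: [int(s), int(e)] for k, (s, e) in p.elements.items()}
    d["tss"] = int(p.tss)
    if p.sigma54_tss is not None:
        d["sigma54_tss"] = int(p.sigma54_tss)
    return d


def _promoter_from_dict(d: dict) -> PlantedPromoter:
    d = dict(d)
    d["elements"] = {k: (int(s), int(e)) for k, (s, e) in d["elements"].items()}
    return PlantedPromoter(**d)


def write_fixture(genome: GenomeModel, counts: CountMatrix, outdir) -> dict:
    """Write FASTA + GFF3 + truth BED + counts TSV + YAML manifest.

    The manifest carries the full truth table and parameters so the fixture
    round-trips losslessly through :func:`read_fixture`.  Returns the
    manifest dict.
    """
    out = io.ensure_dir(outdir)
    io.write_fasta(out / "genome.fa", genome.sequence)
    io.write_gff3(out / "genes.gff3", genome.genes)
    bed_records = []
    for p in genome.promoters:
        core = [iv for name, iv in p.elements.items() if not name.startswith("s54_")]
        span = (min(s for s, _ in core), max(e for _, e in core))
        bed_records.append(("genome", span[0], span[1], p.promoter_type, 0, p.strand))
        s54 = [iv for name, iv in p.elements.items() if name.startswith("s54_")]
        if s54:
            span54 = (min(s for s, _ in s54), max(e for _, e in s54))
            bed_records.append(
                ("genome", span54[0], span54[1],
                 f"{p.promoter_type}:sigma54_site_class_{p.site_class}", 0,
                 p.sigma54_strand)
            )
    bed_records.sort(key=lambda r: (r[1], r[2]))
    io.write_bed(out / "truth.bed", bed_records)
    io.write_tsv(out / "counts.tsv", counts.counts.reset_index())
    manifest = {
        "seed": int(genome.seed),
        "sequence_length": len(genome.sequence),
        "n_genes": len(genome.genes),
        "n_replicates": int(counts.n_replicates),
        "strains": list(counts.strains),
        "params": _params_to_dict(genome.params),
        "promoters": [_promoter_to_dict(p) for p in genome.promoters],
        "files": ["genome.fa", "genes.gff3", "truth.bed", "counts.tsv"],
    }
    io.write_yaml(out / "manifest.yaml", manifest)
    return manifest


def _params_to_dict(params: SimParams) -> dict:
    d = asdict(params)
    for key in ("gene_length_range", "intergenic_range", "repressed_classes"):
        d[key] = list(d[key])
    return d


def _params_from_dict(d: dict) -> SimParams:
    d = dict(d)
    for key in ("gene_length_range", "intergenic_range", "repressed_classes"):
        d[key] = tuple(d[key])
    return SimParams(**d)


def read_fixture(outdir) -> tuple[GenomeModel, CountMatrix]:
    """Inverse of :func:`write_fixture`."""
    out = io.ensure_dir(outdir)
    manifest = io.read_yaml(out / "manifest.yaml")
    _, sequence = io.read_fasta(out / "genome.fa")
    genes = [Gene(*rec) for rec in io.read_gff3(out / "genes.gff3")]
    promoters = [_promoter_from_dict(d) for d in manifest["promoters"]]
    genome = GenomeModel(
        sequence, genes, promoters, int(manifest["seed"]),
        _params_from_dict(manifest["params"]),
    )
    genome.validate()
    df = io.read_tsv(out / "counts.tsv").set_index("gene_id")
    counts = CountMatrix(
        df, tuple(manifest["strains"]), int(manifest["n_replicates"])
    )
    return genome, counts
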