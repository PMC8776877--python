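"""Synthetic phage-selection experiment with known planted truth.

The generator emits a complete, self-consistent toy dataset in the on-disk
formats every downstream stage consumes — reference FASTA, category-tagged
GFF3, per-clone VCF and per-base coverage TSV, per-clone contig FASTA,
typing CSV and long-format growth CSV — together with the ground truth used
to validate recovery. The design mirrors the selection experiment it
emulates: a bacterial population is exposed to single phages or cocktails,
surviving clones are picked per treatment arm, and each clone may acquire

* point mutations in functional gene categories (receptor-category
  mutations break the corresponding receptor and confer resistance to the
  phages that use it; a dual-receptor phage is resisted when either of its
  receptors is broken),
* one large chromosomal deletion, always containing a fixed core interval
  that carries an LPS-synthesis gene (deletion therefore implies LPS-phage
  resistance),
* carried (pseudolysogenic) phage genomes, only for phages the clone
  resists — emitted as full-length extra contigs,
* or, at a configurable rate, resistance with no detectable genomic cause
  (mirroring resistant clones without distinguishable modifications).

Deletion and carrier clones grow with a multiplicatively reduced logistic
rate, so fitness analysis can recover the planted penalties. Everything is
driven by one seeded generator: identical configs give byte-identical
datasets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotations import GENE_CATEGORIES, Gene
from .panel import DEFAULT_PANEL, PhageDef, StrainDef
from .variants import VariantRecord

#: Receptor-relevant categories: breaking them confers phage resistance.
RECEPTOR_CATEGORIES = {"LPS": "LPS", "T4P": "T4P"}

BASES = np.array(list("ACGT"))


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


def _default_treatments():
    # single phages and cocktails, as applied to the clinical populations
    return (
        frozenset({"LUZ7"}),
        frozenset({"KTN6"}),
        frozenset({"phiKZ"}),
        frozenset({"PA5oct"}),
        frozenset({"KTN6", "LUZ7"}),
        frozenset({"KTN6", "phiKZ"}),
        frozenset({"KTN6", "LUZ7", "phiKZ"}),
    )


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic selection experiment.

    Defaults follow the emulated experimental design: ten colonies picked
    per treatment arm, triplicate growth curves over 18 h at 20-minute
    intervals, inoculum 1e5 CFU/ml, phage titer 1e7 PFU/ml. Genomic scales
    (200 kbp genome, 20-60 kbp deletions over a 6 kbp core) are a reduced
    but structurally faithful stand-in for a full-size chromosome.
    """

    seed: int
    genome_length: int = 200_000
    n_genes_per_category: int = 4
    gene_length: int = 900
    n_clones_per_treatment: int = 10
    n_controls: int = 3
    panel: tuple = DEFAULT_PANEL
    treatments: tuple = field(default_factory=_default_treatments)
    p_point_mutation: float = 0.3
    p_deletion: float = 0.23
    deletion_core: tuple = (90_000, 96_000)
    deletion_size_range: tuple = (20_000, 60_000)
    p_carrier: float = 0.3
    p_no_mechanism: float = 0.15
    growth_noise_sd: float = 0.02
    fitness_penalty_deletion: float = 0.7
    fitness_penalty_carrier: float = 0.8
    depth: int = 30
    inoculum_cfu: float = 1e5
    phage_titer_pfu: float = 1e7
    strain_name: str = "SIM"

    def __post_init__(self):
        cs, ce = self.deletion_core
        if not (0 <= cs < ce <= self.genome_length):
            raise SimConfigError(
                f"deletion_core {self.deletion_core} outside genome "
                f"[0, {self.genome_length})"
            )
        lo, hi = self.deletion_size_range
        if not (0 < lo <= hi):
            raise SimConfigError(f"bad deletion_size_range {self.deletion_size_range}")
        if lo < ce - cs:
            raise SimConfigError("deletion_size_range min must cover the core")
        if hi > self.genome_length:
            raise SimConfigError("deletion larger than genome")
        for name in ("p_point_mutation", "p_deletion", "p_carrier", "p_no_mechanism"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise SimConfigError(f"{name}={p} outside [0, 1]")
        for name in ("fitness_penalty_deletion", "fitness_penalty_carrier"):
            f_ = getattr(self, name)
            if not 0.0 < f_ <= 1.0:
                raise SimConfigError(f"{name}={f_} outside (0, 1]")
        if self.genome_length <= 0 or self.gene_length <= 0:
            raise SimConfigError("genome_length and gene_length must be > 0")
        if self.n_clones_per_treatment < 0 or self.n_controls < 0:
            raise SimConfigError("clone counts must be >= 0")
        panel_names = {p.name for p in self.panel}
        for t in self.treatments:
            if not t <= panel_names:
                raise SimConfigError(
                    f"treatment {sorted(t)} uses phages outside the panel"
                )

    @property
    def strain(self) -> StrainDef:
        return StrainDef(self.strain_name)


@dataclass
class CloneTruth:
    """Planted ground truth for one clone."""

    clone_id: str
    origin: str
    treatment: frozenset
    variants: list
    deletion: tuple | None
    carried: frozenset
    resistant: frozenset
    growth_factor: float
    no_mechanism: bool = False


@dataclass
class SimTruth:
    """Planted ground truth for the whole dataset."""

    config: SimConfig
    genes: list
    clones: dict  # clone_id -> CloneTruth

    def clone_ids(self):
        return sorted(self.clones)

    def to_json(self, path) -> None:
        payload = {
            "seed": self.config.seed,
            "strain": self.config.strain_name,
            "genes": [asdict(g) for g in self.genes],
            "clones": {
                cid: {
                    "origin": t.origin,
                    "treatment": sorted(t.treatment),
                    "variants": [asdict(v) for v in t.variants],
                    "deletion": list(t.deletion) if t.deletion else None,
                    "carried": sorted(t.carried),
                    "resistant": sorted(t.resistant),
                    "growth_factor": t.growth_factor,
                    "no_mechanism": t.no_mechanism,
                }
                for cid, t in sorted(self.clones.items())
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


@dataclass(frozen=True)
class DatasetPaths:
    """Locations of every file a generated dataset comprises."""

    root: Path
    reference: Path
    gff3: Path
    category_map: Path
    phages: Path
    vcf_dir: Path
    coverage_dir: Path
    contig_dir: Path
    typing_csv: Path
    growth_csv: Path
    truth_json: Path


# ---------------------------------------------------------------------------
# gene layout

def _place_genes(config: SimConfig) -> list:
    """Deterministic gene layout.

    One LPS gene (galU-like) and one "other" gene (hmgA-like) sit inside
    the deletion core so every planted deletion removes them; all remaining
    genes are placed outside the maximal deletion footprint so point
    mutations never fall in a deleted region.
    """
    cs, ce = config.deletion_core
    max_size = config.deletion_size_range[1]
    span_lo = max(0, ce - max_size)
    span_hi = min(config.genome_length, cs + max_size)
    gl = config.gene_length

    core_mid = (cs + ce) // 2
    if ce - cs < 2 * gl + 20:
        raise SimConfigError("deletion core too small to host its two genes")
    genes = [
        Gene("galU", "chromosome", cs + 10, cs + 10 + gl, "+", "LPS"),
        Gene("hmgA", "chromosome", core_mid, core_mid + gl, "-", "other"),
    ]

    # remaining slots: uniform grid over [0, span_lo) and [span_hi, genome)
    n_rest = sum(
        config.n_genes_per_category - (1 if cat in ("LPS", "other") else 0)
        for cat in GENE_CATEGORIES
    )
    slots = []
    left = span_lo - gl - 10
    right = config.genome_length - span_hi - gl - 10
    total = max(left, 0) + max(right, 0)
    if n_rest > 0 and total < n_rest * (gl + 50):
        raise SimConfigError("genome too small for the requested gene count")
    step = total // max(n_rest, 1)
    pos = 5
    for _ in range(n_rest):
        if pos < left:
            start = pos
        else:
            start = span_hi + 5 + (pos - left)
        slots.append(start)
        pos += step

    i = 0
    for cat in GENE_CATEGORIES:
        n_needed = config.n_genes_per_category - (1 if cat in ("LPS", "other") else 0)
        for j in range(n_needed):
            start = slots[i]
            idx = j + (2 if cat in ("LPS", "other") else 1)
            genes.append(
                Gene(
                    f"{cat}_{idx}",
                    "chromosome",
                    start,
                    start + gl,
                    "+" if i % 2 == 0 else "-",
                    cat,
                )
            )
            i += 1
    return sorted(genes, key=lambda g: g.start)


# ---------------------------------------------------------------------------
# per-clone truth

def _plant_clone(
    clone_id, origin, treatment, config: SimConfig, genes, reference, rng
) -> CloneTruth:
    by_cat: dict = {}
    for g in genes:
        by_cat.setdefault(g.category, []).append(g)
    panel_by = {p.name: p for p in config.panel}

    no_mechanism = bool(rng.random() < config.p_no_mechanism)
    deletion = None
    variants: list = []
    broken: set = set()

    if not no_mechanism:
        if rng.random() < config.p_deletion:
            lo, hi = config.deletion_size_range
            size = int(rng.integers(lo, hi + 1))
            cs, ce = config.deletion_core
            start_lo = max(0, ce - size)
            start_hi = min(cs, config.genome_length - size)
            start = int(rng.integers(start_lo, start_hi + 1))
            deletion = (start, start + size)
            broken.add("LPS")  # the core LPS-synthesis gene is lost

        for cat in GENE_CATEGORIES:
            if rng.random() >= config.p_point_mutation:
                continue
            candidates = [
                g
                for g in by_cat.get(cat, [])
                if deletion is None or not (deletion[0] < g.end and g.start < deletion[1])
            ]
            if not candidates:
                continue
            gene = candidates[int(rng.integers(len(candidates)))]
            pos0 = int(rng.integers(gene.start, gene.end))
            ref_base = reference[pos0]
            effect = ("missense", "nonsense", "frameshift")[int(rng.integers(3))]
            if effect == "frameshift":
                alt = ref_base + str(rng.choice(BASES))
            else:
                others = [b for b in "ACGT" if b != ref_base]
                alt = others[int(rng.integers(3))]
            variants.append(
                VariantRecord(
                    clone_id=clone_id,
                    chrom="chromosome",
                    pos=pos0 + 1,
                    ref=ref_base,
                    alt=alt,
                    effect=effect,
                    gene_id=gene.gene_id,
                )
            )
            receptor = RECEPTOR_CATEGORIES.get(cat)
            if receptor:
                broken.add(receptor)

    resistant = {
        name for name, p in panel_by.items() if p.receptors & broken
    }
    if no_mechanism:
        resistant |= set(treatment)

    carried = set()
    for phage in sorted(treatment):
        if phage in resistant and rng.random() < config.p_carrier:
            carried.add(phage)

    factor = 1.0
    if deletion is not None:
        factor *= config.fitness_penalty_deletion
    if carried:
        factor *= config.fitness_penalty_carrier

    return CloneTruth(
        clone_id=clone_id,
        origin=origin,
        treatment=frozenset(treatment),
        variants=variants,
        deletion=deletion,
        carried=frozenset(carried),
        resistant=frozenset(resistant),
        growth_factor=factor,
        no_mechanism=no_mechanism,
    )


def build_truth(config: SimConfig) -> tuple:
    """Draw the reference genome and the full planted truth (no files)."""
    rng = np.random.default_rng(config.seed)
    reference = "".join(rng.choice(BASES, size=config.genome_length))
    genes = _place_genes(config)

    clones: dict = {}
    for ti, treatment in enumerate(config.treatments):
        label = "+".join(sorted(treatment))
        for j in range(config.n_clones_per_treatment):
            cid = f"t{ti}_{label}_{j:02d}"
            clones[cid] = _plant_clone(
                cid, "biofilm", treatment, config, genes, reference, rng
            )
    for j in range(config.n_controls):
        cid = f"control_{j:02d}"
        clones[cid] = CloneTruth(
            cid, "control", frozenset(), [], None, frozenset(), frozenset(), 1.0
        )
    wt = f"{config.strain_name}_wt"
    clones[wt] = CloneTruth(
        wt, "wild_type", frozenset(), [], None, frozenset(), frozenset(), 1.0
    )
    return reference, SimTruth(config=config, genes=genes, clones=clones)


# ---------------------------------------------------------------------------
# growth curves

def logistic_od(times, factor: float, od0: float = 0.01,
                carrying_capacity: float = 1.2, rate: float = 0.012):
    """Noiseless logistic OD600 curve; ``rate`` in 1/min, scaled by ``factor``."""
    t = np.asarray(times, dtype=float)
    k = carrying_capacity
    return k * od0 / (od0 + (k - od0) * np.exp(-rate * factor * t))


def growth_time_grid():
    """18 h at 20-minute intervals, including the initial read (55 samples)."""
    return np.arange(0, 1081, 20, dtype=float)


def plant_growth_curves(truth: SimTruth, config: SimConfig,
                        n_replicates: int = 3) -> pd.DataFrame:
    """Triplicate noisy logistic growth curves for every clone.

    OD = logistic(rate x clone growth factor) + N(0, growth_noise_sd),
    truncated at zero. Returns the long-format table
    (clone, replicate, time_min, od600).
    """
    rng = np.random.default_rng(config.seed + 1_000_003)
    times = growth_time_grid()
    frames = []
    for cid in sorted(truth.clones):
        clean = logistic_od(times, truth.clones[cid].growth_factor)
        for rep in range(1, n_replicates + 1):
            noise = rng.normal(0.0, config.growth_noise_sd, size=times.size) \
                if config.growth_noise_sd > 0 else 0.0
            od = np.maximum(clean + noise, 0.0)
            frames.append(pd.DataFrame({
                "clone": cid,
                "replicate": rep,
                "time_min": times.astype(int),
                "od600": od,
            }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# file emission

def _write_fasta(path, records: dict) -> None:
    with open(path, "w") as fh:
        for name in records:
            fh.write(f">{name}\n")
            seq = records[name]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def _write_gff3(path, genes, genome_length: int) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region chromosome 1 {genome_length}\n")
        for g in genes:
            attrs = f"ID={g.gene_id};category={g.category}"
            fh.write(
                f"chromosome\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


_VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chromosome,length={length}>
##INFO=<ID=EFF,Number=1,Type=String,Description="Predicted effect class">
##INFO=<ID=GENE,Number=1,Type=String,Description="Affected gene">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def _write_vcf(path, clone: CloneTruth, genome_length: int) -> None:
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(length=genome_length))
        for v in sorted(clone.variants, key=lambda v: v.pos):
            info = f"EFF={v.effect}"
            if v.gene_id:
                info += f";GENE={v.gene_id}"
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\n"
            )


def _write_coverage(path, clone: CloneTruth, config: SimConfig) -> None:
    depths = np.full(config.genome_length, config.depth, dtype=np.int64)
    if clone.deletion is not None:
        depths[clone.deletion[0] : clone.deletion[1]] = 0
    df = pd.DataFrame({
        "contig": "chromosome",
        "pos": np.arange(1, config.genome_length + 1),
        "depth": depths,
    })
    df.to_csv(path, sep="\t", header=False, index=False)


def _clone_chromosome(reference: str, clone: CloneTruth) -> str:
    seq = list(reference)
    for v in clone.variants:
        if len(v.ref) == 1 and len(v.alt) == 1:  # apply substitutions only
            seq[v.pos - 1] = v.alt
    if clone.deletion is not None:
        s, e = clone.deletion
        seq = seq[:s] + seq[e:]
    return "".join(seq)


def generate_dataset(config: SimConfig, outdir) -> tuple:
    """Generate the full on-disk dataset; returns (DatasetPaths, SimTruth)."""
    outdir = Path(outdir)
    reference, truth = build_truth(config)

    paths = DatasetPaths(
        root=outdir,
        reference=outdir / "reference.fasta",
        gff3=outdir / "genes.gff3",
        category_map=outdir / "gene_categories.tsv",
        phages=outdir / "phages.fasta",
        vcf_dir=outdir / "vcf",
        coverage_dir=outdir / "coverage",
        contig_dir=outdir / "contigs",
        typing_csv=outdir / "typing.csv",
        growth_csv=outdir / "growth.csv",
        truth_json=outdir / "truth.json",
    )
    for d in (outdir, paths.vcf_dir, paths.coverage_dir, paths.contig_dir):
        d.mkdir(parents=True, exist_ok=True)

    _write_fasta(paths.reference, {"chromosome": reference})
    _write_gff3(paths.gff3, truth.genes, config.genome_length)
    with open(paths.category_map, "w") as fh:
        for g in truth.genes:
            fh.write(f"{g.gene_id}\t{g.category}\n")

    # phage genomes: drawn once from a seed-derived stream, independent of
    # clone sampling so cohort size does not change the phage sequences
    prng = np.random.default_rng(config.seed + 2_000_003)
    phage_seqs = {
        p.name: "".join(prng.choice(BASES, size=p.genome_length))
        for p in sorted(config.panel, key=lambda p: p.name)
    }
    _write_fasta(paths.phages, phage_seqs)

    typing_rows = []
    for cid in sorted(truth.clones):
        clone = truth.clones[cid]
        _write_vcf(paths.vcf_dir / f"{cid}.vcf", clone, config.genome_length)
        _write_coverage(paths.coverage_dir / f"{cid}.tsv", clone, config)
        contigs = {"chromosome": _clone_chromosome(reference, clone)}
        for phage in sorted(clone.carried):
            contigs[f"phage_{phage}"] = phage_seqs[phage]
        _write_fasta(paths.contig_dir / f"{cid}.fasta", contigs)
        row = {
            "clone_id": cid,
            "strain": config.strain_name,
            "origin": clone.origin,
            "treatment": ";".join(sorted(clone.treatment)),
        }
        for p in config.panel:
            row[p.name] = "R" if p.name in clone.resistant else "S"
        typing_rows.append(row)
    pd.DataFrame(typing_rows).to_csv(paths.typing_csv, index=False)

    growth = plant_growth_curves(truth, config)
    growth.to_csv(paths.growth_csv, index=False, float_format="%.6f")
    truth.to_json(paths.truth_json)
    return paths, truth
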