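"""Per-clone variant filtering and functional classification.

Variant calls (SNPs and small indels) arrive per clone, either as VCF v4.2
with the predicted effect in a custom ``EFF`` INFO key, or as a Snippy-style
TSV. The pipeline mirrors the filtering applied to phage-resistant clones:

1. drop every variant that also occurs in an untreated control isolate
   (exact match on chromosome, position, ref and alt allele);
2. keep only missense, nonsense and frameshift effects, optionally rescuing
   intergenic variants that fall in the promoter window upstream of a gene;
3. assign each retained variant to one of six functional gene categories
   (LPS synthesis, EPS/mucoidity, type IV pili, flagella, global regulatory,
   other) and tabulate per-clone and per-strain frequencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import pandas as pd
from cyvcf2 import VCF

from .annotations import GENE_CATEGORIES, Gene, GeneCategoryMap

logger = logging.getLogger(__name__)

EFFECTS = ("missense", "nonsense", "frameshift", "synonymous", "intergenic", "other")

#: Effect classes retained by the functional filter.
IMPACTFUL_EFFECTS = frozenset({"missense", "nonsense", "frameshift"})


@dataclass(frozen=True)
class VariantRecord:
    """One called mutation, 1-based coordinates."""

    clone_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    effect: str
    gene_id: str | None = None
    promoter_flag: bool = False

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect {self.effect!r}")
        if self.gene_id is None and self.effect not in ("intergenic", "other"):
            raise ValueError(
                f"effect {self.effect!r} requires a gene_id (pos {self.pos})"
            )

    @property
    def key(self):
        """Allele identity used for control matching."""
        return (self.chrom, self.pos, self.ref, self.alt)


def _normalize_effect(effect: str, context: str) -> str:
    eff = (effect or "").strip().lower()
    if eff in EFFECTS:
        return eff
    logger.warning("unknown effect %r (%s); mapped to 'other'", effect, context)
    return "other"


def read_variants(path, dialect: str = "vcf", clone_id: str | None = None) -> list:
    """Read one clone's variant calls.

    Parameters
    ----------
    path : path-like
        VCF v4.2 file (``dialect="vcf"``, effect in INFO key ``EFF``, gene in
        INFO key ``GENE``) or Snippy-style TSV (``dialect="snippy_tsv"``,
        columns CHROM, POS, TYPE, REF, ALT, EFFECT, GENE).
    clone_id : str, optional
        Clone identifier; defaults to the file stem.
    """
    from pathlib import Path

    if clone_id is None:
        clone_id = Path(path).stem.removesuffix(".vcf")
    if dialect == "vcf":
        return _read_vcf(path, clone_id)
    if dialect == "snippy_tsv":
        return _read_snippy(path, clone_id)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_vcf(path, clone_id) -> list:
    records = []
    for v in VCF(str(path)):
        effect = _normalize_effect(
            v.INFO.get("EFF"), f"{path}:{v.CHROM}:{v.POS}"
        )
        gene = v.INFO.get("GENE") or None
        if gene is None and effect not in ("intergenic", "other"):
            effect = "other"
        records.append(
            VariantRecord(
                clone_id=clone_id,
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alt=v.ALT[0] if v.ALT else ".",
                effect=effect,
                gene_id=gene,
            )
        )
    return records


def _read_snippy(path, clone_id) -> list:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"CHROM", "POS", "REF", "ALT", "EFFECT"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            pos = int(row.POS)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path} line {i}: bad POS {row.POS!r}") from exc
        effect = _normalize_effect(row.EFFECT, f"{path} line {i}")
        gene = getattr(row, "GENE", None)
        gene = gene if isinstance(gene, str) and gene else None
        if gene is None and effect not in ("intergenic", "other"):
            effect = "other"
        records.append(
            VariantRecord(
                clone_id=clone_id,
                chrom=row.CHROM,
                pos=pos,
                ref=row.REF,
                alt=row.ALT,
                effect=effect,
                gene_id=gene,
            )
        )
    return records


def filter_controls(variants, control_variants) -> list:
    """Drop variants that also occur in untreated control isolates.

    A variant is removed iff some control variant matches it exactly on
    (chrom, pos, ref, alt); survivors keep their input order.
    """
    control_keys = {v.key for v in control_variants}
    return [v for v in variants if v.key not in control_keys]


def filter_effects(
    variants,
    include_promoter: bool = True,
    promoter_window: int = 100,
    genes: list | None = None,
) -> list:
    """Keep impactful variants (missense / nonsense / frameshift).

    With ``include_promoter``, intergenic variants within ``promoter_window``
    bp upstream of a gene's transcription start (strand-aware) are also
    retained, flagged as promoter variants and assigned to that gene.
    """
    if promoter_window <= 0:
        raise ValueError("promoter_window must be > 0")
    retained = []
    for v in variants:
        if v.effect in IMPACTFUL_EFFECTS:
            retained.append(v)
        elif include_promoter and v.effect == "intergenic" and genes:
            gene = _promoter_gene(v, genes, promoter_window)
            if gene is not None:
                retained.append(
                    replace(v, gene_id=gene.gene_id, promoter_flag=True)
                )
    return retained


def _promoter_gene(v: VariantRecord, genes, window: int):
    """Gene whose upstream promoter window contains the variant, if any."""
    pos0 = v.pos - 1
    best = None
    best_dist = None
    for g in genes:
        if g.chrom != v.chrom:
            continue
        if g.strand != "-":
            dist = g.start - pos0  # bases upstream of the start
        else:
            dist = pos0 - (g.end - 1)
        if 1 <= dist <= window and (best_dist is None or dist < best_dist):
            best, best_dist = g, dist
    return best


@dataclass
class ClassifiedVariantTable:
    """Retained variants with categories plus per-clone tallies.

    Attributes
    ----------
    variants : pandas.DataFrame
        One row per retained variant with its assigned category.
    clone_counts : pandas.DataFrame
        Clones x six categories; number of retained variants per cell.
    clone_stats : pandas.DataFrame
        Per clone: ``n_variants``, ``n_genes_hit``, ``n_categories_hit``,
        ``multi_category`` (variants in 2-3 genes from different functional
        groups) and ``multi_gene_one_category`` (two or more genes hit within
        a single group).
    """

    variants: pd.DataFrame
    clone_counts: pd.DataFrame
    clone_stats: pd.DataFrame


def classify_variants(
    variants, gene_map: GeneCategoryMap, clones=None
) -> ClassifiedVariantTable:
    """Assign functional categories and tabulate per-clone counts.

    ``clones`` optionally lists every clone that should appear in the output
    tables (clones without retained variants then show zero counts).
    """
    rows = [
        {
            "clone_id": v.clone_id,
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "effect": v.effect,
            "gene_id": v.gene_id,
            "promoter_flag": v.promoter_flag,
            "category": gene_map[v.gene_id],
        }
        for v in variants
    ]
    vdf = pd.DataFrame(
        rows,
        columns=[
            "clone_id", "chrom", "pos", "ref", "alt", "effect",
            "gene_id", "promoter_flag", "category",
        ],
    )
    if clones is None:
        clones = sorted(vdf["clone_id"].unique())
    clones = list(clones)

    counts = (
        vdf.groupby(["clone_id", "category"]).size().unstack(fill_value=0)
        if len(vdf)
        else pd.DataFrame()
    )
    counts = counts.reindex(index=clones, columns=list(GENE_CATEGORIES), fill_value=0)
    counts = counts.fillna(0).astype(int)

    stats = pd.DataFrame(index=pd.Index(clones, name="clone_id"))
    stats["n_variants"] = counts.sum(axis=1)
    by_clone = vdf.groupby("clone_id")
    genes_hit = by_clone["gene_id"].nunique().reindex(clones).fillna(0).astype(int)
    cats_hit = by_clone["category"].nunique().reindex(clones).fillna(0).astype(int)
    stats["n_genes_hit"] = genes_hit
    stats["n_categories_hit"] = cats_hit
    stats["multi_category"] = (genes_hit >= 2) & (cats_hit >= 2)
    multi_one = pd.Series(False, index=stats.index)
    if len(vdf):
        per = vdf.groupby(["clone_id", "category"])["gene_id"].nunique()
        hits = per[per >= 2].index.get_level_values("clone_id").unique()
        multi_one.loc[multi_one.index.intersection(hits)] = True
    stats["multi_gene_one_category"] = multi_one
    return ClassifiedVariantTable(variants=vdf, clone_counts=counts, clone_stats=stats)


def strain_frequency_table(
    tables: dict, clone_lists: dict, treatment_labels: dict | None = None
) -> pd.DataFrame:
    """Per strain x treatment x category: fraction of clones hit.

    Parameters
    ----------
    tables : mapping strain -> ClassifiedVariantTable
    clone_lists : mapping strain -> sequence of clone ids analysed
        Must include clones with zero retained variants.
    treatment_labels : mapping clone_id -> label, optional
        Treatment group per clone; all clones share one group when omitted.
    """
    rows = []
    for strain, table in tables.items():
        clones = list(clone_lists[strain])
        if not clones:
            raise ValueError(f"strain {strain!r}: no clones listed")
        counts = table.clone_counts.reindex(clones, fill_value=0)
        labels = pd.Series(
            [treatment_labels.get(c, "all") if treatment_labels else "all"
             for c in clones],
            index=counts.index,
        )
        for label, grp in counts.groupby(labels):
            n = len(grp)
            row = {"strain": strain, "treatment": label, "n_clones": n}
            for cat in GENE_CATEGORIES:
                row[f"frac_{cat}"] = float((grp[cat] > 0).mean())
            row["frac_no_variants"] = float((grp.sum(axis=1) == 0).mean())
            rows.append(row)
    return pd.DataFrame(rows)
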