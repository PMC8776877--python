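"""Gene annotations (GFF3) and gene -> functional-category maps."""

from __future__ import annotations

from dataclasses import dataclass

import gffutils
import pandas as pd

#: The six functional gene categories used to group resistance mutations.
GENE_CATEGORIES = (
    "LPS",
    "EPS_mucoidity",
    "T4P",
    "flagella",
    "global_regulatory",
    "other",
)


@dataclass(frozen=True)
class Gene:
    """One annotated gene; coordinates 0-based half-open, as in BED."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    category: str = "other"

    @property
    def tss(self) -> int:
        """0-based position of the transcription start (strand-aware)."""
        return self.start if self.strand != "-" else self.end - 1


def read_gff3(path) -> list:
    """Load gene features from a GFF3 file.

    Reads ``gene`` features; the functional category is taken from a
    ``category=`` attribute when present, defaulting to ``other``.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        category = feat.attributes.get("category", ["other"])[0]
        genes.append(
            Gene(
                gene_id=gene_id,
                chrom=feat.seqid,
                start=feat.start - 1,  # GFF3 is 1-based inclusive
                end=feat.end,
                strand=feat.strand or "+",
                category=category,
            )
        )
    return genes


class GeneCategoryMap:
    """Total map gene_id -> category, defaulting to ``other``."""

    def __init__(self, mapping=None):
        mapping = dict(mapping or {})
        bad = set(mapping.values()) - set(GENE_CATEGORIES)
        if bad:
            raise ValueError(f"unknown categor(ies) {sorted(bad)}; "
                             f"allowed: {GENE_CATEGORIES}")
        self._map = mapping

    def __getitem__(self, gene_id) -> str:
        if gene_id is None:
            return "other"
        return self._map.get(gene_id, "other")

    def __len__(self):
        return len(self._map)

    @classmethod
    def from_tsv(cls, path) -> "GeneCategoryMap":
        """Read a two-column (gene_id, category) TSV."""
        df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "category"],
                         comment="#", dtype=str)
        return cls(dict(zip(df["gene_id"], df["category"])))

    @classmethod
    def from_genes(cls, genes) -> "GeneCategoryMap":
        """Build the map from ``category=`` attributes of annotated genes."""
        return cls({g.gene_id: g.category for g in genes})

    def to_tsv(self, path) -> None:
        pd.DataFrame(sorted(self._map.items())).to_csv(
            path, sep="\t", header=False, index=False
        )
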