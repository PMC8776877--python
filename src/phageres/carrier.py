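"""Carrier-state (pseudolysogeny) detection from assembled contigs.

A lytic phage is *carried* by a resistant population when its complete
genome persists extrachromosomally without integration. Operationally a
clone is called a carrier of a phage when (i) one of the clone's assembled
contigs contains essentially the full phage genome — measured as canonical
k-mer breadth, the fraction of the phage genome's canonical k-mers found in
the contig — and (ii) the clone is phenotypically resistant to that phage
in the typing matrix. A full contig in a still-sensitive clone is not a
carrier state (the phage may simply be propagating lytically).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

from .panel import DEFAULT_PANEL, TABLE_PHAGE_ORDER, panel_by_name

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

REASONS = ("carrier", "contig_absent", "phenotypically_sensitive")


def canonical_kmers(seq: str, k: int) -> set:
    """Canonical (strand-independent) k-mer set of a sequence.

    Each window is represented by the lexicographic minimum of itself and
    its reverse complement; windows containing non-ACGT characters are
    skipped. K-mers are returned 2-bit encoded (A=0, C=1, G=2, T=3, most
    significant base first), an encoding that preserves lexicographic
    order, so set intersections match string-level canonical k-mer sets.
    """
    seq = seq.upper()
    if len(seq) < k:
        return set()
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    code = np.full(raw.size, -1, dtype=np.int64)
    for i, ch in enumerate(b"ACGT"):
        code[raw == ch] = i
    win = np.lib.stride_tricks.sliding_window_view(code, k)
    win = win[(win >= 0).all(axis=1)]
    if win.size == 0:
        return set()
    weights = (1 << (2 * np.arange(k - 1, -1, -1))).astype(np.int64)
    fwd = win @ weights
    rev = (3 - win)[:, ::-1] @ weights  # reverse complement
    return set(np.minimum(fwd, rev).tolist())


@dataclass(frozen=True)
class ContigMatch:
    """k-mer containment of one phage genome in one clone's assembly."""

    clone_id: str
    phage_name: str
    breadth: float
    best_contig: str
    is_full: bool

    def __post_init__(self):
        if not 0.0 <= self.breadth <= 1.0:
            raise ValueError(f"breadth {self.breadth} outside [0, 1]")


@dataclass(frozen=True)
class CarrierCall:
    """Per clone x phage carrier decision."""

    clone_id: str
    phage_name: str
    carrier: bool
    reason: str

    def __post_init__(self):
        if self.reason not in REASONS:
            raise ValueError(f"unknown reason {self.reason!r}")
        if self.carrier != (self.reason == "carrier"):
            raise ValueError("carrier flag inconsistent with reason")


def _as_seq_dict(source) -> dict:
    """Accept a FASTA path or a mapping name -> sequence."""
    if isinstance(source, dict):
        return {name: str(seq) for name, seq in source.items()}
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(source), "fasta")}


def match_contigs(
    contigs,
    phage_genomes,
    k: int = 21,
    min_breadth: float = 0.95,
    clone_id: str = "",
) -> list:
    """Measure k-mer breadth of each phage genome in a clone's contigs.

    Parameters
    ----------
    contigs, phage_genomes : FASTA path or mapping name -> sequence
    k : int
        Odd k-mer size in [11, 31]; canonical k-mers make the measure
        invariant to reverse-complementing any contig.
    min_breadth : float
        Breadth threshold on the single best contig for ``is_full``.

    Returns one :class:`ContigMatch` per phage, using the contig with the
    highest breadth (ties broken by contig name).
    """
    if k % 2 == 0 or not 11 <= k <= 31:
        raise ValueError(f"k must be odd and in [11, 31], got {k}")
    contig_seqs = _as_seq_dict(contigs)
    phage_seqs = _as_seq_dict(phage_genomes)
    contig_kmers = {name: canonical_kmers(s, k) for name, s in contig_seqs.items()}

    matches = []
    for phage, seq in sorted(phage_seqs.items()):
        if len(seq) < k:
            raise ValueError(f"phage {phage!r} genome shorter than k={k}")
        pk = canonical_kmers(seq, k)
        best_contig, best_breadth = "", 0.0
        for name in sorted(contig_kmers):
            breadth = len(pk & contig_kmers[name]) / len(pk)
            if breadth > best_breadth:
                best_contig, best_breadth = name, breadth
        matches.append(
            ContigMatch(
                clone_id=clone_id,
                phage_name=phage,
                breadth=best_breadth,
                best_contig=best_contig,
                is_full=best_breadth >= min_breadth,
            )
        )
    return matches


def call_carriers(matches, typing) -> list:
    """Combine contig containment with the typing phenotype.

    A clone carries a phage iff the full phage contig is present *and* the
    clone is typed resistant (R) to that phage; otherwise the blocking
    condition is recorded as the reason.
    """
    calls = []
    for m in matches:
        if m.clone_id not in typing.meta.index:
            raise KeyError(f"clone {m.clone_id!r} absent from typing matrix")
        resistant = typing.call(m.clone_id, m.phage_name) == "R"
        if m.is_full and resistant:
            calls.append(CarrierCall(m.clone_id, m.phage_name, True, "carrier"))
        elif not m.is_full:
            calls.append(CarrierCall(m.clone_id, m.phage_name, False, "contig_absent"))
        else:
            calls.append(
                CarrierCall(m.clone_id, m.phage_name, False, "phenotypically_sensitive")
            )
    return calls


@dataclass
class CarrierSummary:
    """Carrier-state summary per strain, mirroring the study's table layout.

    ``carriers``/``assessed`` are strain x phage count frames; strain totals
    count *distinct* carrier clones (a clone carrying two phages counts
    once), while the jumbo subtotal counts carrier calls for phages with
    genomes over 200 kbp.
    """

    carriers: pd.DataFrame
    assessed: pd.DataFrame
    strain_totals: pd.Series
    strain_assessed: pd.Series
    jumbo_carrier_calls: pd.Series
    prophage_counts: pd.Series

    def format_table(self) -> pd.DataFrame:
        """Human-readable ``carriers/assessed`` strings plus totals."""
        out = pd.DataFrame(index=self.carriers.index)
        for phage in self.carriers.columns:
            out[phage] = [
                f"{c}/{n}" if n else "-"
                for c, n in zip(self.carriers[phage], self.assessed[phage])
            ]
        out["Total"] = [
            f"{c}/{n}"
            for c, n in zip(self.strain_totals, self.strain_assessed)
        ]
        out["Intact prophages in WT"] = self.prophage_counts
        return out


def summarize_carriers(
    calls, strains, clone_strains, panel=DEFAULT_PANEL
) -> CarrierSummary:
    """Aggregate carrier calls per strain and phage.

    Parameters
    ----------
    calls : list of CarrierCall
        Complete calls for every assessed clone x phage pair; pairs without
        a call count as not assessed (denominators differ per phage when
        treatment arms differ).
    strains : sequence of StrainDef
    clone_strains : mapping clone_id -> strain name
    """
    by_name = panel_by_name(panel)
    phage_order = [p for p in TABLE_PHAGE_ORDER if p in by_name]
    phage_order += [p.name for p in panel if p.name not in phage_order]
    strain_names = [s.name for s in strains]

    carriers = pd.DataFrame(0, index=strain_names, columns=phage_order)
    assessed = pd.DataFrame(0, index=strain_names, columns=phage_order)
    carrier_clones: dict = {s: set() for s in strain_names}
    assessed_clones: dict = {s: set() for s in strain_names}
    jumbo = pd.Series(0, index=strain_names)

    for c in calls:
        strain = clone_strains[c.clone_id]
        if strain not in carriers.index:
            raise KeyError(f"clone {c.clone_id!r}: unknown strain {strain!r}")
        assessed.at[strain, c.phage_name] += 1
        assessed_clones[strain].add(c.clone_id)
        if c.carrier:
            carriers.at[strain, c.phage_name] += 1
            carrier_clones[strain].add(c.clone_id)
            if by_name[c.phage_name].is_jumbo:
                jumbo[strain] += 1

    return CarrierSummary(
        carriers=carriers,
        assessed=assessed,
        strain_totals=pd.Series({s: len(v) for s, v in carrier_clones.items()}),
        strain_assessed=pd.Series({s: len(v) for s, v in assessed_clones.items()}),
        jumbo_carrier_calls=jumbo,
        prophage_counts=pd.Series({s.name: s.prophage_count for s in strains}),
    )
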