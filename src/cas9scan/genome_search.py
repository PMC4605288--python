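"""Enumeration of candidate protospacer sites in a genome.

A Cas9 guide targets a 20-nt protospacer followed immediately (3') by a
protospacer-adjacent motif (PAM).  Off-target binding tolerates many
mismatches (up to 9 here), cleavage fewer (up to 6), so candidate discovery
is a k-mismatch (Hamming) scan of both genomic strands combined with a PAM
admissibility filter.  PAM trinucleotides are classified into three classes
with decreasing Cas9 preference: GGG, then NGG (non-G first base), then NNG
(third base G, second base not G).

Coordinates are 0-based half-open (BED convention) and always cover the
20-nt protospacer only; the PAM lies at ``[end, end+3)`` on the plus strand
and ``[start-3, start)`` on the minus strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO

__all__ = [
    "Mode",
    "PamClass",
    "PAM_PRIORITY",
    "MISMATCH_BUDGET",
    "GuideQuery",
    "PamPolicy",
    "CandidateSite",
    "classify_pam",
    "reverse_complement",
    "read_fasta",
    "read_guides",
    "enumerate_candidates",
    "candidates_to_bed",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_GUIDE_RE = re.compile(r"^[ACGT]{20}$")


class Mode(str, Enum):
    """Prediction mode: dCas9 binding or active Cas9 cleavage."""

    BINDING = "binding"
    CLEAVAGE = "cleavage"


#: Maximum number of protospacer mismatches tolerated per mode.
MISMATCH_BUDGET: dict[Mode, int] = {Mode.BINDING: 9, Mode.CLEAVAGE: 6}


class PamClass(str, Enum):
    GGG = "GGG"
    NGG = "NGG"
    NNG = "NNG"


#: Tie-break priority (lower = preferred): GGG over NGG over NNG.
PAM_PRIORITY: dict[PamClass, int] = {
    PamClass.GGG: 0,
    PamClass.NGG: 1,
    PamClass.NNG: 2,
}


def reverse_complement(seq: str) -> str:
    """Reverse-complement a DNA string (ACGTN, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def classify_pam(trinucleotide: str) -> PamClass | None:
    """Classify a 3-mer into a PAM class, or ``None`` if inadmissible.

    ``GGG`` is literal; ``NGG`` requires G at positions 2-3 with a non-G
    first base; ``NNG`` requires G at position 3 with a non-G second base.
    ``N`` bases never satisfy a required G.

    Raises
    ------
    ValueError
        If the input is not a 3-character uppercase string over ACGTN.
    """
    if not isinstance(trinucleotide, str) or len(trinucleotide) != 3:
        raise ValueError(f"PAM must be a 3-character string, got {trinucleotide!r}")
    if any(c not in "ACGTN" for c in trinucleotide):
        raise ValueError(f"PAM contains characters outside ACGTN: {trinucleotide!r}")
    a, b, c = trinucleotide
    if a == "G" and b == "G" and c == "G":
        return PamClass.GGG
    if b == "G" and c == "G":
        return PamClass.NGG
    if c == "G" and b != "G":
        return PamClass.NNG
    return None


@dataclass(frozen=True)
class GuideQuery:
    """A 20-nt protospacer query plus its prediction mode.

    Parameters
    ----------
    protospacer
        Exactly 20 characters over the strict ACGT alphabet, written 5'->3'
        with position 20 adjacent to the PAM.
    mode
        ``binding`` (budget 9 mismatches) or ``cleavage`` (budget 6).
    label
        Free-text identifier used in outputs.
    """

    protospacer: str
    mode: Mode = Mode.BINDING
    label: str = "guide"

    def __post_init__(self) -> None:
        if not _GUIDE_RE.match(self.protospacer):
            raise ValueError(
                "protospacer must be exactly 20 characters over ACGT, got "
                f"{self.protospacer!r}"
            )
        object.__setattr__(self, "mode", Mode(self.mode))

    @property
    def budget(self) -> int:
        return MISMATCH_BUDGET[self.mode]


@dataclass(frozen=True)
class PamPolicy:
    """Which PAM classes are searched.  NGG (and its GGG sub-class) always
    are; NNG is an explicit opt-in."""

    admit_nng: bool = False

    def admits(self, pam_class: PamClass) -> bool:
        if pam_class in (PamClass.GGG, PamClass.NGG):
            return True
        return pam_class is PamClass.NNG and self.admit_nng


@dataclass(frozen=True)
class CandidateSite:
    """A genomic locus matching a guide within the mismatch budget.

    ``site_seq`` is the 20-nt genomic protospacer read 5'->3' on the strand
    facing the guide; ``pam`` is the trinucleotide immediately 3' of it on
    that strand.  ``mismatch_mask[i]`` compares guide position i to
    ``site_seq`` position i (0-based, position 19 adjacent to the PAM).
    """

    chrom: str
    start: int
    end: int
    strand: str
    site_seq: str
    pam: str
    pam_class: PamClass
    mismatch_mask: tuple[bool, ...]
    n_mismatches: int

    def __post_init__(self) -> None:
        if self.end - self.start != 20:
            raise ValueError("candidate interval must span exactly 20 bases")
        if len(self.mismatch_mask) != 20:
            raise ValueError("mismatch mask must have 20 positions")
        if self.n_mismatches != sum(self.mismatch_mask):
            raise ValueError("n_mismatches inconsistent with mismatch_mask")

    @property
    def sort_key(self) -> tuple[str, int, str]:
        return (self.chrom, self.start, self.strand)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (multi-record, possibly line-wrapped) FASTA into a dict of
    uppercase sequences keyed by record id."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_guides(source: str | Path, mode: Mode = Mode.BINDING) -> list[GuideQuery]:
    """Load guides from a FASTA file, a plain-text file (one 20-mer per
    line), or a raw 20-mer string."""
    mode = Mode(mode)
    if isinstance(source, str) and _GUIDE_RE.match(source.upper()):
        return [GuideQuery(source.upper(), mode)]
    path = Path(source)
    text = path.read_text()
    if text.lstrip().startswith(">"):
        return [
            GuideQuery(str(rec.seq).upper(), mode, label=rec.id)
            for rec in SeqIO.parse(str(path), "fasta")
        ]
    guides = []
    for i, line in enumerate(filter(None, (l.strip() for l in text.splitlines()))):
        guides.append(GuideQuery(line.upper(), mode, label=f"guide{i + 1}"))
    return guides


def _byte_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _pam_class_masks(
    g1: np.ndarray, g2: np.ndarray, g3: np.ndarray, policy: PamPolicy
) -> np.ndarray:
    """Boolean admissibility per window from 'is-G' vectors for the three
    PAM positions."""
    admitted = g2 & g3  # NGG class incl. GGG
    if policy.admit_nng:
        admitted = admitted | (g3 & ~g2)
    return admitted


def _classify_from_flags(g1: bool, g2: bool, g3: bool) -> PamClass:
    if g1 and g2 and g3:
        return PamClass.GGG
    if g2 and g3:
        return PamClass.NGG
    return PamClass.NNG


def enumerate_candidates(
    genome: Mapping[str, str],
    query: GuideQuery,
    policy: PamPolicy = PamPolicy(),
    max_mismatches: int | None = None,
) -> list[CandidateSite]:
    """Enumerate all loci on both strands within the mismatch budget that
    carry an admitted PAM.

    The scan is a vectorized Hamming comparison of every 20-nt window
    against the guide; minus-strand windows are compared after
    reverse-complementing the genomic segment.  Non-ACGT genome bases count
    as mismatches and never satisfy a required PAM G.  Windows whose PAM
    would run off the chromosome end are skipped.  The result is sorted by
    (chrom, start, strand).

    Parameters
    ----------
    genome
        Mapping of chromosome name to uppercase sequence.
    query
        The guide; its mode sets the budget unless ``max_mismatches``
        overrides it.
    policy
        PAM classes to admit (NGG always; NNG optional).
    max_mismatches
        Explicit budget override (useful for exploratory scans).
    """
    budget = query.budget if max_mismatches is None else int(max_mismatches)
    guide = query.protospacer
    g_fwd = _byte_array(guide)
    g_rc = _byte_array(reverse_complement(guide))
    G = ord("G")
    C = ord("C")

    sites: list[CandidateSite] = []
    for chrom in genome:
        seq = genome[chrom].upper()
        L = len(seq)
        if L < 23:
            continue
        arr = _byte_array(seq)
        nwin = L - 22

        # Plus strand: protospacer [i, i+20), PAM [i+20, i+23).
        mm = np.zeros(nwin, dtype=np.int16)
        for p in range(20):
            mm += arr[p : p + nwin] != g_fwd[p]
        pam_ok = _pam_class_masks(
            arr[20 : 20 + nwin] == G,
            arr[21 : 21 + nwin] == G,
            arr[22 : 22 + nwin] == G,
            policy,
        )
        for i in np.flatnonzero((mm <= budget) & pam_ok):
            i = int(i)
            window = seq[i : i + 20]
            pam = seq[i + 20 : i + 23]
            mask = tuple(a != b for a, b in zip(guide, window))
            sites.append(
                CandidateSite(
                    chrom=chrom,
                    start=i,
                    end=i + 20,
                    strand="+",
                    site_seq=window,
                    pam=pam,
                    pam_class=_classify_from_flags(
                        pam[0] == "G", pam[1] == "G", pam[2] == "G"
                    ),
                    mismatch_mask=mask,
                    n_mismatches=int(mm[i]),
                )
            )

        # Minus strand: protospacer [s, s+20) with s in [3, L-20]; the PAM
        # occupies genomic [s-3, s) and reads revcomp on the minus strand,
        # so PAM position t is G iff genomic base s-1-t is C.
        mm = np.zeros(nwin, dtype=np.int16)
        for p in range(20):
            mm += arr[3 + p : 3 + p + nwin] != g_rc[p]
        pam_ok = _pam_class_masks(
            arr[2 : 2 + nwin] == C,
            arr[1 : 1 + nwin] == C,
            arr[0:nwin] == C,
            policy,
        )
        for k in np.flatnonzero((mm <= budget) & pam_ok):
            k = int(k)
            s = k + 3
            site_seq = reverse_complement(seq[s : s + 20])
            pam = reverse_complement(seq[s - 3 : s])
            mask = tuple(a != b for a, b in zip(guide, site_seq))
            sites.append(
                CandidateSite(
                    chrom=chrom,
                    start=s,
                    end=s + 20,
                    strand="-",
                    site_seq=site_seq,
                    pam=pam,
                    pam_class=_classify_from_flags(
                        pam[0] == "G", pam[1] == "G", pam[2] == "G"
                    ),
                    mismatch_mask=mask,
                    n_mismatches=int(mm[k]),
                )
            )
    sites.sort(key=lambda s: s.sort_key)
    return sites


def candidates_to_bed(sites: Iterable[CandidateSite], label: str) -> str:
    """Serialize candidates as BED6 text (name = guide label, score =
    mismatch count)."""
    lines = [
        f"{s.chrom}\t{s.start}\t{s.end}\t{label}\t{s.n_mismatches}\t{s.strand}"
        for s in sites
    ]
    return "\n".join(lines) + ("\n" if lines else "")
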