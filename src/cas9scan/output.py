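"""Prediction records, tab-delimited output, gene annotation and config.

The prediction table has a fixed, documented column order::

    chrom  start  end  strand  sequence  pam  n_mismatches  S  X  S_d  S_f  pam_class  gene

``sequence`` is the 23-character display form: the 20-nt genomic
protospacer with mismatched positions lowercased and matches uppercased,
followed by the 3-nt PAM in uppercase.  Scores print with two decimals;
identical inputs produce byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .chromatin import read_bed_intervals
from .genome_search import CandidateSite, PamClass
from .scoring import ScoredSite, WeightSet

__all__ = [
    "COLUMNS",
    "PredictionRecord",
    "record_from_scored",
    "records_from_scored",
    "write_predictions",
    "parse_predictions",
    "annotate_genes",
    "load_config",
    "weights_from_config",
]

COLUMNS = (
    "chrom",
    "start",
    "end",
    "strand",
    "sequence",
    "pam",
    "n_mismatches",
    "S",
    "X",
    "S_d",
    "S_f",
    "pam_class",
    "gene",
)


def _display_seq(site_seq: str, mismatch_mask: Sequence[bool], pam: str) -> str:
    body = "".join(
        c.lower() if mm else c.upper() for c, mm in zip(site_seq, mismatch_mask)
    )
    return body + pam.upper()


@dataclass(frozen=True)
class PredictionRecord:
    """One output row.  ``display_seq`` encodes the mismatch mask in its
    case pattern (lowercase = mismatch) over the first 20 characters, with
    the PAM appended."""

    chrom: str
    start: int
    end: int
    strand: str
    display_seq: str
    n_mismatches: int
    S: float
    X: int
    S_d: float
    S_f: float
    pam_class: PamClass
    overlapping_gene: str = ""

    def __post_init__(self) -> None:
        if len(self.display_seq) != 23:
            raise ValueError("display_seq must be 23 characters (20 nt + PAM)")
        n_lower = sum(1 for c in self.display_seq[:20] if c.islower())
        if n_lower != self.n_mismatches:
            raise ValueError(
                "lowercase positions in display_seq must equal n_mismatches"
            )

    @property
    def mismatch_mask(self) -> tuple[bool, ...]:
        return tuple(c.islower() for c in self.display_seq[:20])

    @property
    def site_seq(self) -> str:
        return self.display_seq[:20].upper()

    @property
    def pam(self) -> str:
        return self.display_seq[20:]


def record_from_scored(s: ScoredSite, gene: str = "") -> PredictionRecord:
    site = s.site
    return PredictionRecord(
        chrom=site.chrom,
        start=site.start,
        end=site.end,
        strand=site.strand,
        display_seq=_display_seq(site.site_seq, site.mismatch_mask, site.pam),
        n_mismatches=site.n_mismatches,
        S=s.S,
        X=int(s.X),
        S_d=s.S_d,
        S_f=s.S_f,
        pam_class=site.pam_class,
        overlapping_gene=gene,
    )


def records_from_scored(sites: Iterable[ScoredSite]) -> list[PredictionRecord]:
    return [record_from_scored(s) for s in sites]


def _format_row(r: PredictionRecord) -> str:
    return "\t".join(
        (
            r.chrom,
            str(r.start),
            str(r.end),
            r.strand,
            r.display_seq,
            r.pam,
            str(r.n_mismatches),
            f"{r.S:.2f}",
            str(r.X),
            f"{r.S_d:.2f}",
            f"{r.S_f:.2f}",
            r.pam_class.value,
            r.overlapping_gene,
        )
    )


def write_predictions(
    records: Sequence[PredictionRecord],
    destination: str | Path,
    split_pam: bool = False,
) -> list[Path]:
    """Write prediction rows as a tab-delimited file with a header.

    With ``split_pam`` the records are partitioned by PAM class into one
    file per class (suffix ``.GGG.tsv`` etc. on the destination stem),
    mirroring per-PAM output binning; the default is a single merged file.
    Returns the paths written.
    """
    destination = Path(destination)
    header = "\t".join(COLUMNS)
    if not split_pam:
        with destination.open("w") as fh:
            fh.write(header + "\n")
            for r in records:
                fh.write(_format_row(r) + "\n")
        return [destination]
    paths = []
    for cls in PamClass:
        subset = [r for r in records if r.pam_class is cls]
        if not subset:
            continue
        path = destination.with_suffix(f".{cls.value}.tsv")
        with path.open("w") as fh:
            fh.write(header + "\n")
            for r in subset:
                fh.write(_format_row(r) + "\n")
        paths.append(path)
    return paths


def parse_predictions(path: str | Path) -> list[PredictionRecord]:
    """Parse a prediction TSV back into records (round-trips
    :func:`write_predictions` output)."""
    path = Path(path)
    records: list[PredictionRecord] = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != COLUMNS:
            raise ValueError(f"{path}: unexpected header {header}")
        for lineno, line in enumerate(fh, 2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(COLUMNS):
                raise ValueError(f"{path}:{lineno}: expected {len(COLUMNS)} columns")
            records.append(
                PredictionRecord(
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    strand=fields[3],
                    display_seq=fields[4],
                    n_mismatches=int(fields[6]),
                    S=float(fields[7]),
                    X=int(fields[8]),
                    S_d=float(fields[9]),
                    S_f=float(fields[10]),
                    pam_class=PamClass(fields[11]),
                    overlapping_gene=fields[12],
                )
            )
    return records


def annotate_genes(
    records: Sequence[PredictionRecord],
    genes: str | Path | Iterable[tuple[str, int, int, str]],
) -> list[PredictionRecord]:
    """Fill ``overlapping_gene`` with the comma-joined names (in coordinate
    order) of gene intervals overlapping each record by >= 1 bp.

    ``genes`` is a BED file (column 4 = name) or an iterable of
    (chrom, start, end, name).
    """
    if isinstance(genes, (str, Path)):
        path = Path(genes)
        parsed = []
        with path.open() as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ValueError(f"{path}:{lineno}: gene BED needs >= 4 columns")
                try:
                    parsed.append((fields[0], int(fields[1]), int(fields[2]), fields[3]))
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: bad coordinates") from exc
        genes = parsed
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end, name in genes:
        if start >= end:
            raise ValueError(f"invalid gene interval {chrom}:{start}-{end}")
        trees.setdefault(chrom, IntervalTree()).addi(start, end, name)
    out = []
    for r in records:
        tree = trees.get(r.chrom)
        if tree is None:
            out.append(replace(r, overlapping_gene=""))
            continue
        hits = sorted(tree.overlap(r.start, r.end), key=lambda iv: (iv.begin, iv.end))
        out.append(replace(r, overlapping_gene=",".join(iv.data for iv in hits)))
    return out


def load_config(path: str | Path) -> dict[str, str]:
    """Read a plain ``key = value`` config file (one pair per line; ``#``
    comments and blank lines ignored)."""
    cfg: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, value = line.split("=", 1)
        cfg[key.strip()] = value.strip()
    return cfg


def weights_from_config(cfg: Mapping[str, str], base: WeightSet) -> WeightSet:
    """Override weight-set fields from a parsed config mapping.  Recognized
    keys: s1, s2, s3, d, mismatch_limit, dnase_coefficient."""
    kwargs: dict[str, float | int] = {}
    for key in ("s1", "s2", "s3", "d", "dnase_coefficient"):
        if key in cfg:
            kwargs[key] = float(cfg[key])
    if "mismatch_limit" in cfg:
        kwargs["mismatch_limit"] = int(cfg["mismatch_limit"])
    return replace(base, **kwargs)
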