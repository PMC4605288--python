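"""Seeded synthetic fixtures: genomes with planted off-target sites,
per-cell-type peak tracks and gold-standard intervals.

Every module of the package is testable without downloads: a fixture is a
pure function of its spec (identical seeds give identical bytes) and ships
a manifest carrying the ground truth — planted coordinates, mismatch
masks, and the expected candidate set under a stated budget, computed by a
deliberately naive per-base sliding-window scan kept separate from the
vectorized search implementation.

Defaults emulate the study conditions the method was built for: a guide
with off-target loci at a range of mismatch counts (binding tolerates up
to 9, cleavage up to 6), NGG-class PAMs, accessibility tracks from many
cell types in which validated sites tend to sit in commonly open bins, and
gold intervals slightly padded around the true loci so that a contained
20-bp prediction passes full-containment intersection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .genome_search import GuideQuery, Mode, reverse_complement

__all__ = [
    "PlantedSite",
    "SyntheticSpec",
    "Fixture",
    "naive_candidate_scan",
    "generate_fixture",
    "mismatch_ladder_spec",
    "write_fixture",
]

_BASES = "ACGT"


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[i] for i in rng.choice(4, size=length, p=p))


@dataclass(frozen=True)
class PlantedSite:
    """One site to engineer into the genome: which guide positions are
    mutated (0-based, position 19 PAM-proximal), the PAM to install, the
    strand, and whether the site belongs to the gold-standard set."""

    mismatch_positions: tuple[int, ...] = ()
    pam: str = "AGG"
    strand: str = "+"
    gold: bool = False
    accessible: bool = False  # preferentially covered by cell-type peaks

    def __post_init__(self) -> None:
        if any(p < 0 or p > 19 for p in self.mismatch_positions):
            raise ValueError("mismatch positions must lie in 0..19")
        if len(set(self.mismatch_positions)) != len(self.mismatch_positions):
            raise ValueError("duplicate mismatch positions")
        if len(self.pam) != 3 or any(c not in "ACGT" for c in self.pam):
            raise ValueError("PAM must be a 3-mer over ACGT")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a synthetic dataset; generation is a pure
    function of this spec."""

    seed: int
    genome_length: int = 6000
    gc: float = 0.41  # human-like background composition
    chrom: str = "chr1"
    guide: str | None = None  # random 20-mer if None
    planted: tuple[PlantedSite, ...] = ()
    budget: int = 9  # budget the manifest's expected set is computed under
    admit_nng: bool = False
    # accessibility track
    n_cell_types: int = 20
    peaks_per_cell_type: int = 8
    peak_width: int = 400
    accessible_site_prob: float = 0.9  # chance a cell type covers an "accessible" site
    background_site_prob: float = 0.1
    gold_slop: int = 10  # padding of gold intervals around planted sites

    def __post_init__(self) -> None:
        min_len = 40 * max(len(self.planted), 1)
        if self.genome_length < min_len:
            raise ValueError(
                f"genome of {self.genome_length} nt cannot host "
                f"{len(self.planted)} planted sites (needs >= {min_len})"
            )


@dataclass
class Fixture:
    """A generated dataset plus its ground-truth manifest."""

    spec: SyntheticSpec
    genome: dict[str, str]
    guide: GuideQuery
    peak_sets: list[list[tuple[str, int, int]]]
    gold_intervals: list[tuple[str, int, int]]
    manifest: dict


def naive_candidate_scan(
    genome: dict[str, str],
    guide: str,
    budget: int,
    admit_nng: bool = False,
) -> list[tuple[str, int, str, int, tuple[bool, ...], str]]:
    """Reference candidate enumeration by per-base sliding-window scan.

    Returns (chrom, start, strand, n_mismatches, mask, pam) tuples sorted
    by (chrom, start, strand).  Written independently of the vectorized
    search (plain string comparison, inline PAM logic) so the two can
    cross-check each other.
    """

    def pam_admitted(p: str) -> bool:
        if p[1] == "G" and p[2] == "G":
            return True
        return admit_nng and p[2] == "G" and p[1] != "G"

    hits = []
    for chrom, seq in genome.items():
        seq = seq.upper()
        L = len(seq)
        for i in range(L - 22):
            window = seq[i : i + 20]
            pam = seq[i + 20 : i + 23]
            if pam_admitted(pam):
                mask = tuple(a != b for a, b in zip(guide, window))
                if sum(mask) <= budget:
                    hits.append((chrom, i, "+", sum(mask), mask, pam))
        rc = reverse_complement(seq)
        for j in range(L - 22):
            window = rc[j : j + 20]
            pam = rc[j + 20 : j + 23]
            if pam_admitted(pam):
                mask = tuple(a != b for a, b in zip(guide, window))
                if sum(mask) <= budget:
                    # position j on the reverse strand maps to forward-start
                    # L - j - 20 of the 20-mer window
                    hits.append((chrom, L - j - 20, "-", sum(mask), mask, pam))
    hits.sort(key=lambda h: (h[0], h[1], h[2]))
    return hits


def _mutate(rng: np.random.Generator, guide: str, positions: tuple[int, ...]) -> str:
    site = list(guide)
    for p in positions:
        choices = [b for b in _BASES if b != guide[p]]
        site[p] = choices[int(rng.integers(0, 3))]
    return "".join(site)


def _plant(
    genome: list[str],
    pos: int,
    site_seq: str,
    pam: str,
    strand: str,
) -> tuple[int, int]:
    """Install a site so its protospacer occupies [pos, pos+20) forward
    coordinates; returns that interval."""
    if strand == "+":
        genome[pos : pos + 20] = list(site_seq)
        genome[pos + 20 : pos + 23] = list(pam)
    else:
        genome[pos : pos + 20] = list(reverse_complement(site_seq))
        genome[pos - 3 : pos] = list(reverse_complement(pam))
    return pos, pos + 20


def generate_fixture(spec: SyntheticSpec) -> Fixture:
    """Generate a dataset from a spec.

    Planted sites are installed in evenly spaced blocks (randomly jittered
    within each block).  If the random background would corrupt a planted
    site — i.e. its realized mismatch count differs from the requested one,
    which can only happen through overlap or an accidental better match
    over the same window — the whole genome is redrawn from a derived
    seed.  The manifest records the ground truth and the expected candidate
    set under ``spec.budget``, computed with :func:`naive_candidate_scan`.
    """
    for attempt in range(20):
        rng = np.random.default_rng([spec.seed % (2**31), attempt])
        guide_seq = spec.guide or _random_seq(rng, 20, spec.gc)
        genome_chars = list(_random_seq(rng, spec.genome_length, spec.gc))

        n_sites = len(spec.planted)
        planted_rows = []
        ok = True
        if n_sites:
            block = spec.genome_length // n_sites
            for idx, ps in enumerate(spec.planted):
                lo = idx * block + 5
                hi = (idx + 1) * block - 28
                pos = int(rng.integers(lo, hi))
                site_seq = _mutate(rng, guide_seq, ps.mismatch_positions)
                start, end = _plant(genome_chars, pos, site_seq, ps.pam, ps.strand)
                planted_rows.append(
                    {
                        "chrom": spec.chrom,
                        "start": start,
                        "end": end,
                        "strand": ps.strand,
                        "site_seq": site_seq,
                        "pam": ps.pam,
                        "mismatch_mask": [p in ps.mismatch_positions for p in range(20)],
                        "n_mismatches": len(ps.mismatch_positions),
                        "gold": ps.gold,
                        "accessible": ps.accessible,
                    }
                )
        genome = {spec.chrom: "".join(genome_chars)}

        # verify each planted site survived generation verbatim
        for row in planted_rows:
            s, e = row["start"], row["end"]
            seg = genome[spec.chrom][s:e]
            realized = seg if row["strand"] == "+" else reverse_complement(seg)
            if realized != row["site_seq"]:
                ok = False
                break
        if ok:
            break
    else:
        raise RuntimeError("could not generate a collision-free fixture in 20 attempts")

    expected = naive_candidate_scan(genome, guide_seq, spec.budget, spec.admit_nng)

    # accessibility peaks: each cell type covers accessible planted sites
    # with high probability, other planted sites with low probability, plus
    # random background peaks
    peak_sets: list[list[tuple[str, int, int]]] = []
    for _ in range(spec.n_cell_types):
        peaks: list[tuple[str, int, int]] = []
        for row in planted_rows:
            prob = (
                spec.accessible_site_prob
                if row["accessible"]
                else spec.background_site_prob
            )
            if rng.random() < prob:
                center = (row["start"] + row["end"]) // 2
                half = spec.peak_width // 2
                peaks.append(
                    (
                        spec.chrom,
                        max(0, center - half),
                        min(spec.genome_length, center + half),
                    )
                )
        for _ in range(spec.peaks_per_cell_type):
            s = int(rng.integers(0, max(spec.genome_length - spec.peak_width, 1)))
            peaks.append((spec.chrom, s, s + spec.peak_width))
        peaks.sort()
        peak_sets.append(peaks)

    gold = [
        (
            row["chrom"],
            max(0, row["start"] - spec.gold_slop),
            min(spec.genome_length, row["end"] + spec.gold_slop),
        )
        for row in planted_rows
        if row["gold"]
    ]

    manifest = {
        "seed": spec.seed,
        "guide": guide_seq,
        "budget": spec.budget,
        "admit_nng": spec.admit_nng,
        "genome_length": spec.genome_length,
        "planted": planted_rows,
        "expected_candidates": [
            {"chrom": c, "start": s, "strand": st, "n_mismatches": nm}
            for c, s, st, nm, _, _ in expected
        ],
    }
    return Fixture(
        spec=spec,
        genome=genome,
        guide=GuideQuery(guide_seq, Mode.BINDING, label="synthetic"),
        peak_sets=peak_sets,
        gold_intervals=gold,
        manifest=manifest,
    )


def mismatch_ladder_spec(
    seed: int,
    counts: tuple[int, ...] = tuple(range(13)),
    pam: str = "AGG",
    genome_length: int = 8000,
) -> SyntheticSpec:
    """Spec with one planted site per mismatch count, PAM-distal mutations
    first (positions filled 5'->3'), all with the same PAM."""
    planted = tuple(
        PlantedSite(mismatch_positions=tuple(range(c)), pam=pam, gold=(c <= 6))
        for c in counts
    )
    return SyntheticSpec(
        seed=seed, genome_length=genome_length, planted=planted, budget=12
    )


def weight_recovery_fixture(
    seed: int,
    target: tuple[float, float, float] = (5, 70, 50),
    axes: tuple[tuple[float, ...], ...] = (
        (0, 5, 10, 15, 20),
        (50, 60, 70, 80, 90),
        (30, 40, 50, 60, 70),
    ),
    top_n: int = 20,
    pool_size: int = 200,
    max_attempts: int = 200,
):
    """Candidate pool and gold set whose top-N containment objective is
    uniquely maximized at ``target`` over the given grid axes.

    Construction: ``top_n`` gold candidates plus exactly one decoy, all
    synthetic loci on one chromosome with random mismatch masks.  The base
    score is linear in (s1, s2, s3), so each mask reduces to a coefficient
    vector; masks are drawn (seeded) until the decoy scores strictly below
    every gold mask at the target weights but strictly above at least one
    gold mask at every other grid point.  With top_n + 1 candidates the
    objective then equals top_n exactly at the target and is smaller
    everywhere else — uniqueness is verified exhaustively at build time,
    not assumed.  The axes must not contain a point proportional to the
    target (proportional weights induce the identical ranking).

    Returns (candidates, gold_intervals, axes, top_n, target).
    """
    import itertools

    from .genome_search import CandidateSite, PamClass
    from .scoring import WeightSet, base_score

    guide = "ACGTACGTACGTACGTACGT"
    target_v = np.array([float(v) for v in target])
    points = np.array(
        [
            p
            for p in itertools.product(*axes)
            if tuple(float(v) for v in p) != tuple(target_v)
        ],
        dtype=float,
    )

    def coeffs(mask: tuple[bool, ...]) -> np.ndarray:
        return np.array(
            [
                base_score(mask, WeightSet(1, 0, 0)),
                base_score(mask, WeightSet(0, 1, 0)),
                base_score(mask, WeightSet(0, 0, 1)),
            ]
        )

    for attempt in range(max_attempts):
        rng = np.random.default_rng([seed % (2**31), 13, attempt])
        pool: list[tuple[bool, ...]] = []
        seen: set[tuple[int, ...]] = set()
        while len(pool) < pool_size:
            n_mm = int(rng.integers(2, 7))
            pos = tuple(sorted(rng.choice(20, size=n_mm, replace=False).tolist()))
            if pos in seen:
                continue
            seen.add(pos)
            pool.append(tuple(p in pos for p in range(20)))
        C = np.array([coeffs(m) for m in pool])
        S_target = C @ target_v
        chosen = None
        for di in range(pool_size):
            above = np.flatnonzero(S_target > C[di] @ target_v + 1e-9)
            if len(above) < top_n:
                continue
            # the lowest-scoring golds above the decoy give the tightest cut
            gold = above[np.argsort(S_target[above])][:top_n]
            S_gold = C[gold] @ points.T
            S_decoy = C[di] @ points.T
            if (S_gold.min(axis=0) < S_decoy - 1e-9).all():
                chosen = (di, gold)
                break
        if chosen is None:
            continue
        di, gold = chosen
        order = list(gold) + [di]  # decoy last -> largest start, loses ties
        candidates = []
        for rank, idx in enumerate(order):
            mask = pool[idx]
            start = 100 * (rank + 1)
            site_seq = "".join(
                ("T" if g != "T" else "A") if mm else g for g, mm in zip(guide, mask)
            )
            candidates.append(
                CandidateSite(
                    chrom="chr1",
                    start=start,
                    end=start + 20,
                    strand="+",
                    site_seq=site_seq,
                    pam="AGG",
                    pam_class=PamClass.NGG,
                    mismatch_mask=mask,
                    n_mismatches=sum(mask),
                )
            )
        gold_intervals = [
            ("chr1", c.start - 5, c.end + 5) for c in candidates[:top_n]
        ]
        return candidates, gold_intervals, axes, top_n, target
    raise RuntimeError(
        f"no uniquely-recoverable weight fixture found in {max_attempts} attempts"
    )


def enrichment_track_fixture(
    seed: int,
    genome_length: int = 200_000,
    bin_width: int = 200,
    n_cell_types: int = 125,
    n_hot_regions: int = 6,
    hot_prob: float = 0.96,
    peaks_per_cell_type: int = 40,
    min_hot_x: int = 100,
):
    """A binned accessibility track with a handful of 'hot' regions open
    in nearly all of ``n_cell_types`` cell types (X >= ``min_hot_x``) over
    a low-X random background.

    Returns (track, genome_sizes, hot_intervals) where ``hot_intervals``
    are the hot bins verified to have X >= ``min_hot_x``.
    """
    from .chromatin import build_bin_track

    rng = np.random.default_rng([seed % (2**31), 11])
    hot_starts = sorted(
        int(s) * bin_width * 10
        for s in rng.choice(genome_length // (bin_width * 10) - 1, size=n_hot_regions, replace=False)
    )
    hot_regions = [(s, s + 2 * bin_width) for s in hot_starts]
    peak_sets = []
    for _ in range(n_cell_types):
        peaks = [
            ("chr1", s, e) for s, e in hot_regions if rng.random() < hot_prob
        ]
        for _ in range(peaks_per_cell_type):
            s = int(rng.integers(0, genome_length - 2 * bin_width))
            peaks.append(("chr1", s, s + 2 * bin_width))
        peak_sets.append(peaks)
    track = build_bin_track(peak_sets, bin_width=bin_width)
    hot_intervals = []
    for s, e in hot_regions:
        for idx in range(s // bin_width, (e - 1) // bin_width + 1):
            if track.x_at("chr1", idx) >= min_hot_x:
                hot_intervals.append(
                    ("chr1", idx * bin_width, (idx + 1) * bin_width)
                )
    if not hot_intervals:
        raise RuntimeError("no hot bin reached the requested cell-type count")
    return track, {"chr1": genome_length}, hot_intervals


def _wrap_fasta(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def write_fixture(fixture: Fixture, outdir: str | Path) -> dict[str, Path]:
    """Write a fixture to disk: genome FASTA, guide text, one BED per cell
    type, gold BED, and the JSON manifest.  Byte-deterministic."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    genome_path = outdir / "genome.fa"
    with genome_path.open("w") as fh:
        for chrom in sorted(fixture.genome):
            fh.write(f">{chrom}\n{_wrap_fasta(fixture.genome[chrom])}\n")
    paths["genome"] = genome_path

    guide_path = outdir / "guide.txt"
    guide_path.write_text(fixture.guide.protospacer + "\n")
    paths["guide"] = guide_path

    peak_dir = outdir / "peaks"
    peak_dir.mkdir(exist_ok=True)
    peak_paths = []
    for i, peaks in enumerate(fixture.peak_sets):
        p = peak_dir / f"celltype_{i:03d}.bed"
        with p.open("w") as fh:
            for chrom, s, e in peaks:
                fh.write(f"{chrom}\t{s}\t{e}\n")
        peak_paths.append(p)
    paths["peak_dir"] = peak_dir

    gold_path = outdir / "gold.bed"
    with gold_path.open("w") as fh:
        for chrom, s, e in fixture.gold_intervals:
            fh.write(f"{chrom}\t{s}\t{e}\n")
    paths["gold"] = gold_path

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(fixture.manifest, indent=1, sort_keys=True))
    paths["manifest"] = manifest_path
    return paths
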