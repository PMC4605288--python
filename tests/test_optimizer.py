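import itertools
from dataclasses import replace

import pandas as pd
import pytest

from cas9scan import (
    BINDING_WEIGHTS,
    GoldStandardSet,
    GridSpec,
    build_bin_track,
    grid_search,
    objective_top_n_overlap,
    train_chromatin_weight,
)
from cas9scan.fixtures import weight_recovery_fixture
from test_chromatin import make_site


@pytest.fixture(scope="module")
def recovery():
    return weight_recovery_fixture(seed=424242)


def test_gridspec_validation():
    with pytest.raises(ValueError):
        GridSpec(s1_values=())
    with pytest.raises(ValueError):
        GridSpec(s1_values=(5, 5))
    with pytest.raises(ValueError):
        GridSpec(s1_values=(-1, 5))


def test_gold_standard_set(tmp_path):
    gold = GoldStandardSet([("chr1", 100, 200), ("chr1", 150, 250)])
    assert len(gold) == 2
    assert gold.contains("chr1", 120, 140)
    assert gold.contains("chr1", 160, 240)  # inside the second interval
    assert not gold.contains("chr1", 90, 110)  # partial overlap only
    assert not gold.contains("chr2", 120, 140)
    bed = tmp_path / "gold.bed"
    bed.write_text("chr1\t0\t50\n")
    assert GoldStandardSet.from_bed(bed).contains("chr1", 10, 30)


def test_objective_trivial_cases():
    sites = [make_site(100 * i, n_mm=i % 3) for i in range(10)]
    empty = GoldStandardSet([])
    assert objective_top_n_overlap(sites, BINDING_WEIGHTS, empty, top_n=5) == 0
    everything = GoldStandardSet([("chr1", 0, 10_000)])
    # top_n beyond the candidate count saturates to counting all sites
    assert objective_top_n_overlap(sites, BINDING_WEIGHTS, everything, top_n=1000) == 10
    with pytest.raises(ValueError):
        objective_top_n_overlap(sites, BINDING_WEIGHTS, everything, top_n=0)


def test_objective_counts_predictions_not_gold_intervals():
    # two predictions inside one gold interval count twice
    sites = [make_site(100), make_site(130)]
    gold = GoldStandardSet([("chr1", 90, 160)])
    assert objective_top_n_overlap(sites, BINDING_WEIGHTS, gold, top_n=10) == 2


def test_objective_invariant_under_order(recovery):
    candidates, gold_iv, _, top_n, _ = recovery
    gold = GoldStandardSet(gold_iv)
    a = objective_top_n_overlap(candidates, BINDING_WEIGHTS, gold, top_n=top_n)
    b = objective_top_n_overlap(candidates[::-1], BINDING_WEIGHTS, gold, top_n=top_n)
    assert a == b


def test_single_point_grid():
    sites = [make_site(0)]
    gold = GoldStandardSet([("chr1", 0, 30)])
    grid = GridSpec((5,), (70,), (50,), top_n=10)
    res = grid_search(sites, gold, grid, BINDING_WEIGHTS)
    assert (res.best_weights.s1, res.best_weights.s2, res.best_weights.s3) == (5, 70, 50)
    assert len(res.table) == 1


def test_all_zero_objective_warns():
    sites = [make_site(0)]
    gold = GoldStandardSet([("chr2", 0, 30)])  # never hit
    grid = GridSpec((0, 10), (0, 10), (0, 10), stop_drop=0, top_n=5)
    res = grid_search(sites, gold, grid, BINDING_WEIGHTS)
    assert res.warning is not None
    assert (res.best_weights.s1, res.best_weights.s2, res.best_weights.s3) == (0, 0, 0)


def test_parameter_recovery(recovery):
    """The grid search recovers the weights the gold set was engineered
    around, and its table equals exhaustive enumeration."""
    candidates, gold_iv, axes, top_n, target = recovery
    gold = GoldStandardSet(gold_iv)
    grid = GridSpec(*axes, top_n=top_n)
    res = grid_search(candidates, gold, grid, BINDING_WEIGHTS)
    w = res.best_weights
    assert (w.s1, w.s2, w.s3) == tuple(float(v) for v in target)
    # oracle: plain exhaustive enumeration of the same grid
    brute = {}
    for p in itertools.product(*axes):
        wt = replace(BINDING_WEIGHTS, s1=p[0], s2=p[1], s3=p[2])
        brute[tuple(float(v) for v in p)] = objective_top_n_overlap(
            candidates, wt, gold, top_n=top_n
        )
    table = {(r.s1, r.s2, r.s3): r.objective for r in res.table.itertuples()}
    assert table == brute
    best_obj = table[(w.s1, w.s2, w.s3)]
    assert best_obj == max(brute.values())
    assert sum(1 for v in brute.values() if v == best_obj) == 1


def test_returned_optimum_dominates_table(recovery):
    candidates, gold_iv, axes, top_n, _ = recovery
    gold = GoldStandardSet(gold_iv)
    res = grid_search(candidates, gold, GridSpec(*axes, top_n=top_n), BINDING_WEIGHTS)
    w = res.best_weights
    best_row = res.table[
        (res.table.s1 == w.s1) & (res.table.s2 == w.s2) & (res.table.s3 == w.s3)
    ]
    assert best_row.objective.iloc[0] == res.table.objective.max()


def test_boundary_expansion(recovery):
    """When the optimum sits on an axis boundary the grid extends with
    uniform spacing until the frontier objective has dropped enough."""
    candidates, gold_iv, axes, top_n, target = recovery
    gold = GoldStandardSet(gold_iv)
    # truncate the s1 axis so the target weight is its upper boundary
    s1_axis = tuple(v for v in axes[0] if v <= target[0])
    grid = GridSpec(s1_axis, axes[1], axes[2], expansion_step=5, stop_drop=1, top_n=top_n)
    res = grid_search(candidates, gold, grid, BINDING_WEIGHTS)
    w = res.best_weights
    assert (w.s1, w.s2, w.s3) == tuple(float(v) for v in target)
    assert res.table.s1.max() > target[0]  # the axis actually grew


def test_table_serialization(tmp_path, recovery):
    candidates, gold_iv, axes, top_n, _ = recovery
    gold = GoldStandardSet(gold_iv)
    res = grid_search(candidates, gold, GridSpec(*axes, top_n=top_n), BINDING_WEIGHTS)
    out = tmp_path / "table.tsv"
    res.write_table(out)
    back = pd.read_csv(out, sep="\t")
    assert list(back.columns) == ["s1", "s2", "s3", "objective"]
    assert len(back) == len(res.table)


def test_train_chromatin_weight_cases():
    # gold sites have a slightly worse base score but open chromatin;
    # decoys outrank them until d grows
    gold_sites = [make_site(100 * i, n_mm=2) for i in range(5)]
    decoys = [make_site(10_000 + 100 * i, n_mm=1) for i in range(5)]
    sites = gold_sites + decoys
    gold = GoldStandardSet([("chr1", s.start - 5, s.end + 5) for s in gold_sites])
    open_peaks = [("chr1", 0, 600)]  # covers the gold block only
    track = build_bin_track([open_peaks] * 125, bin_width=200)

    best_d, table = train_chromatin_weight(
        sites, gold, track, d_values=[0, 10, 20, 40], base_weights=BINDING_WEIGHTS, top_n=5
    )
    assert best_d > 0
    assert table.objective.max() == 5

    # single value -> itself
    d, _ = train_chromatin_weight(
        sites, gold, track, d_values=[7], base_weights=BINDING_WEIGHTS, top_n=5
    )
    assert d == 7

    # all-zero track: objective constant in d, smallest d wins
    zero = build_bin_track([[]], bin_width=200)
    d, table = train_chromatin_weight(
        sites, gold, zero, d_values=[0, 10, 20], base_weights=BINDING_WEIGHTS, top_n=5
    )
    assert d == 0
    assert table.objective.nunique() == 1

    with pytest.raises(ValueError):
        train_chromatin_weight(sites, gold, track, [], BINDING_WEIGHTS)
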