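"""Resampling overlap-enrichment test and compendium preprocessing."""

import numpy as np
import pandas as pd
import pytest

from evoko.overlap import (
    LineEffects,
    exclude_ubiquitous,
    filter_lines,
    observed_overlap,
    resample_null,
)


def _line(lid, clustered, distributed):
    return LineEffects(line_id=lid, clustered=dict(clustered), distributed=dict(distributed))


def _effect_table(genes, sig_genes):
    return pd.DataFrame(
        {
            "gene": genes,
            "log2fc": 1.0,
            "p_raw": 0.01,
            "p_adj": 0.01,
            "direction": 1,
            "significant": [g in sig_genes for g in genes],
            "tested": True,
        }
    )


class TestExcludeUbiquitous:
    def test_never_responding_gene_never_excluded(self):
        genes = [f"g{i}" for i in range(50)]
        tables = [_effect_table(genes, {"g0"}) for _ in range(20)]
        assert "g1" not in exclude_ubiquitous(tables)

    def test_gene_significant_in_half_the_lines_is_excluded(self):
        genes = [f"g{i}" for i in range(100)]
        tables = [_effect_table(genes, {"g0"} if i < 50 else set()) for i in range(100)]
        assert "g0" in exclude_ubiquitous(tables)

    def test_cap_equals_top_fraction(self):
        # 10% of genes respond in 20% of lines; exclusion = exactly that 10%
        genes = [f"g{i:03d}" for i in range(100)]
        hot = set(genes[:10])
        tables = [_effect_table(genes, hot if i < 20 else set()) for i in range(100)]
        assert exclude_ubiquitous(tables) == hot

    def test_requires_enough_lines(self):
        with pytest.raises(ValueError):
            exclude_ubiquitous([_effect_table(["a"], set())] * 5)


class TestFilterLines:
    @pytest.mark.parametrize("n_clustered, kept", [(19, False), (20, True)])
    def test_boundary(self, n_clustered, kept):
        ln = _line("x", {f"c{i}": 1 for i in range(n_clustered)}, {"d": 1})
        assert (ln in filter_lines([ln])) is kept

    def test_empty(self):
        assert filter_lines([]) == []


class TestObservedOverlap:
    def test_identical_sets(self):
        c = {f"g{i}": 1 for i in range(7)}
        lines = [_line(f"l{j}", c, {"d": 1}) for j in range(3)]
        assert observed_overlap(lines) == 7

    def test_direction_flip_kills_overlap(self):
        c = {f"g{i}": 1 for i in range(7)}
        flipped = {g: -d for g, d in c.items()}
        lines = [_line("a", c, {"d": 1}), _line("b", flipped, {"d": 1})]
        assert observed_overlap(lines) == 0

    def test_disjoint_sets(self):
        lines = [
            _line("a", {"x": 1}, {"d": 1}),
            _line("b", {"y": 1}, {"d": 1}),
        ]
        assert observed_overlap(lines) == 0

    def test_monotone_in_lines(self, rng):
        lines = []
        for j in range(4):
            genes = rng.choice(100, size=30, replace=False)
            lines.append(_line(f"l{j}", {f"g{i}": 1 for i in genes}, {"d": 1}))
        counts = [observed_overlap(lines[: k + 1]) for k in range(1, 4)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_needs_two_lines(self):
        with pytest.raises(ValueError):
            observed_overlap([_line("a", {"x": 1}, {"d": 1})])


def _planted_group(rng, n_lines=4, shared=20, extra_clustered=10, n_distributed=80):
    """Lines sharing a planted clustered core; distributed scattered."""
    pool = [f"bg{i}" for i in range(2000)]
    shared_genes = {f"core{i}": 1 if i % 2 else -1 for i in range(shared)}
    lines = []
    for j in range(n_lines):
        extra = rng.choice(pool, size=extra_clustered, replace=False)
        clustered = dict(shared_genes, **{g: 1 for g in extra})
        dist_genes = rng.choice([g for g in pool if g not in clustered], size=n_distributed, replace=False)
        distributed = {g: int(rng.choice([-1, 1])) for g in dist_genes}
        lines.append(_line(f"l{j}", clustered, distributed))
    return lines


class TestResampleNull:
    def test_determinism_under_seed(self, rng):
        lines = _planted_group(rng)
        a = resample_null(lines, n_iter=200, seed=42)
        b = resample_null(lines, n_iter=200, seed=42)
        assert a.ci99 == b.ci99
        assert np.array_equal(a.null_overlaps, b.null_overlaps)

    def test_planted_shared_core_is_significant(self, rng):
        lines = _planted_group(rng)
        res = resample_null(lines, n_iter=1000, seed=1)
        assert res.observed_overlap == 20
        assert res.fold > 5
        assert res.significant
        assert res.normalization_case == "i"

    def test_null_mean_invariant_to_pool_relabeling(self, rng):
        lines = _planted_group(rng)
        res_a = resample_null(lines, n_iter=1000, seed=3)
        relabeled = [
            _line(
                ln.line_id,
                ln.clustered,
                {f"perm_{i}": d for i, d in enumerate(ln.distributed.values())},
            )
            for ln in lines
        ]
        res_b = resample_null(relabeled, n_iter=1000, seed=3)
        spread = 3 * max(res_a.null_overlaps.std(), 1.0) / np.sqrt(1000)
        assert abs(res_a.null_mean - res_b.null_mean) <= max(spread, 0.2)

    def test_exchangeable_sets_fold_near_one(self, rng):
        """Swapping exchangeable clustered/distributed roles leaves fold ~ 1."""
        shared = {f"s{i}": 1 for i in range(30)}
        lines = []
        for j in range(3):
            # clustered and distributed drawn from the same distribution,
            # both containing the shared core
            extra_c = {f"c{j}_{i}": 1 for i in range(20)}
            extra_d = {f"d{j}_{i}": 1 for i in range(20)}
            half = dict(list(shared.items())[:15])
            other_half = {g: d for g, d in shared.items() if g not in half}
            lines.append(_line(f"l{j}", dict(half, **extra_c), dict(other_half, **extra_d)))
        res = resample_null(lines, n_iter=2000, seed=9)
        swapped = [_line(ln.line_id, ln.distributed, ln.clustered) for ln in lines]
        res_sw = resample_null(swapped, n_iter=2000, seed=9)
        assert res.observed_overlap == res_sw.observed_overlap == 15
        assert abs(res.fold - 1.0) <= 0.35 and abs(res_sw.fold - 1.0) <= 0.35

    def test_case_ii_subsamples_clustered_side(self):
        lines = [
            _line("a", {f"c{i}": 1 for i in range(30)}, {f"d{i}": 1 for i in range(10)}),
            _line("b", {f"c{i}": 1 for i in range(30)}, {f"d{i}": 1 for i in range(10)}),
        ]
        res = resample_null(lines, n_iter=100, seed=0)
        assert res.normalization_case == "ii"
        assert res.observed_overlap == 10  # the distributed overlap
        assert res.null_overlaps.max() <= 10  # subsampled to the smaller size

    def test_case_iii_mixed_with_replacement(self):
        lines = [
            _line("a", {f"c{i}": 1 for i in range(5)}, {f"d{i}": 1 for i in range(20)}),
            _line("b", {f"c{i}": 1 for i in range(8)}, {f"d{i}": 1 for i in range(3)}),
        ]
        res = resample_null(lines, n_iter=100, seed=0)
        assert res.normalization_case == "iii"

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            resample_null(
                [_line("a", {"x": 1}, {}), _line("b", {"x": 1}, {"d": 1})], n_iter=10, seed=0
            )
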