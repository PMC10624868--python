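import itertools
import math

import numpy as np
import pytest

from prizenet import enrichment as en
from prizenet.errors import ParameterError
from prizenet.omics_io import GeneSetLibrary


def universe_of(n):
    return frozenset(f"g{i:02d}" for i in range(n))


class TestFisherPvalue:
    def test_worked_example_20(self):
        uni = sorted(universe_of(20))
        module = set(uni[:5])
        term = set(uni[:4]) | {uni[10]}  # overlap 4
        p = en.fisher_pvalue(module, term, uni)
        assert p == pytest.approx(76 / 15504, rel=0, abs=1e-15)

    def test_zero_overlap_is_one(self):
        uni = sorted(universe_of(10))
        assert en.fisher_pvalue(uni[:3], uni[5:8], uni) == 1.0

    def test_small_universe(self):
        uni = sorted(universe_of(4))
        p = en.fisher_pvalue(uni[:2], uni[:2], uni)
        assert p == pytest.approx(1 / 6, rel=0, abs=1e-15)

    def test_outside_universe_rejected(self):
        with pytest.raises(ParameterError):
            en.fisher_pvalue({"alien"}, {"g00"}, universe_of(3))

    def test_matches_scipy_hypergeom(self):
        from scipy.stats import hypergeom

        rng = np.random.default_rng(6)
        uni = sorted(universe_of(40))
        for _ in range(30):
            module = set(
                rng.choice(uni, size=int(rng.integers(1, 15)), replace=False)
            )
            term = set(
                rng.choice(uni, size=int(rng.integers(1, 15)), replace=False)
            )
            k = len(module & term)
            ref = hypergeom.sf(k - 1, 40, len(term), len(module))
            assert en.fisher_pvalue(module, term, uni) == pytest.approx(ref)


class TestRankZscore:
    def _library(self, uni):
        uni = sorted(uni)
        return GeneSetLibrary(
            {
                "T1": frozenset(uni[:6]),
                "T2": frozenset(uni[6:12]),
                "T3": frozenset(uni[3:9]),
            }
        )

    def test_deterministic(self):
        uni = universe_of(30)
        lib = self._library(uni)
        module = frozenset(sorted(uni)[:6])
        a = en.rank_zscore(lib, module, uni, n_permutations=20, seed=4)
        b = en.rank_zscore(lib, module, uni, n_permutations=20, seed=4)
        assert a == b

    def test_matching_term_ranks_first_with_negative_z(self):
        uni = universe_of(30)
        lib = self._library(uni)
        module = frozenset(sorted(uni)[:6])  # identical to T1
        out = en.rank_zscore(lib, module, uni, n_permutations=50, seed=1)
        rank, z = out["T1"]
        assert rank == 1.0
        assert z < 0  # far better than its permutation-expected rank

    def test_z_formula(self):
        assert en._z(4.0, 10.0, 2.0) == -3.0
        assert en._z(10.0, 10.0, 2.0) == 0.0

    def test_too_few_permutations_rejected(self):
        uni = universe_of(20)
        with pytest.raises(ParameterError):
            en.rank_zscore(self._library(uni), set(), uni, n_permutations=5)

    def test_module_exceeding_universe_rejected(self):
        uni = universe_of(10)
        lib = GeneSetLibrary({"T": frozenset(sorted(uni)[:2])})
        with pytest.raises(ParameterError):
            en.rank_zscore(lib, universe_of(12), uni)


class TestCombinedScore:
    @pytest.mark.parametrize(
        "p, z, expected",
        [
            (math.exp(-2), -3.0, 6.0),
            (1.0, 5.0, 0.0),
            (0.01, -2.0, -math.log(0.01) * 2.0),
        ],
    )
    def test_examples(self, p, z, expected):
        assert en.combined_score(p, z) == pytest.approx(expected)

    def test_invalid_p_rejected(self):
        with pytest.raises(ParameterError):
            en.combined_score(0.0, 1.0)


class TestEnrich:
    def test_records_internally_consistent(self):
        uni = universe_of(40)
        lib = GeneSetLibrary(
            {
                "GOOD": frozenset(sorted(uni)[:8]),
                "OTHER": frozenset(sorted(uni)[20:30]),
            }
        )
        module = frozenset(sorted(uni)[:8])
        records = en.enrich(lib, module, uni, n_permutations=30, seed=2)
        assert records[0].term == "GOOD"
        for r in records:
            assert abs(r.combined - math.log(r.p) * r.z) <= 1e-9
            assert r.overlap_genes <= lib[r.term]

    def test_self_term_achieves_minimum_p(self):
        uni = universe_of(50)
        module = frozenset(sorted(uni)[:7])
        lib = GeneSetLibrary(
            {
                "SELF": module,
                "A": frozenset(sorted(uni)[10:20]),
                "B": frozenset(sorted(uni)[25:30]),
            }
        )
        records = en.enrich(lib, module, uni, n_permutations=20, seed=0)
        pmin = min(r.p for r in records)
        assert next(r for r in records if r.term == "SELF").p == pmin

    def test_bh_across_terms_flag(self):
        uni = universe_of(30)
        lib = GeneSetLibrary(
            {
                "A": frozenset(sorted(uni)[:5]),
                "B": frozenset(sorted(uni)[5:10]),
            }
        )
        records = en.enrich(
            lib, frozenset(sorted(uni)[:5]), uni,
            n_permutations=20, seed=0, bh_across_terms=True,
        )
        assert all(r.p_adjusted is not None for r in records)
        assert all(r.p_adjusted >= r.p - 1e-15 for r in records)

    def test_tsv_output(self, tmp_path):
        uni = universe_of(30)
        lib = GeneSetLibrary({"A": frozenset(sorted(uni)[:5])})
        records = en.enrich(
            lib, frozenset(sorted(uni)[:5]), uni, n_permutations=20, seed=0
        )
        en.write_enrichment(records, tmp_path / "e.tsv")
        lines = (tmp_path / "e.tsv").read_text().splitlines()
        assert lines[0].startswith("module\tterm\tp\tz")
        assert len(lines) == 2


class TestFisherEnumerationOracle:
    def test_exhaustive_agreement_small_universes(self):
        # brute force: count module draws with overlap >= k
        for n_univ in (5, 8):
            uni = sorted(universe_of(n_univ))
            for k_term in range(1, n_univ + 1):
                term = set(uni[:k_term])
                for n_mod in range(1, n_univ + 1):
                    module = set(uni[-n_mod:])
                    k = len(module & term)
                    hits = total = 0
                    for draw in itertools.combinations(uni, n_mod):
                        total += 1
                        if len(set(draw) & term) >= k:
                            hits += 1
                    assert en.fisher_pvalue(module, term, uni) == pytest.approx(
                        hits / total, rel=0, abs=1e-12
                    )
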