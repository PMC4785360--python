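import itertools

import numpy as np
import pandas as pd
import pytest

from dranet import mdc, simulate
from dranet.cluster import RESISTANT, SENSITIVE
from dranet.exceptions import ConfigError, DegenerateInputError
from dranet.io import GeneSetCollection
from dranet.mdc import (MDCAnalysis, compute_mdc, filter_modules, mdc_fdr,
                        module_connectivity, rank_modules_across_drugs)
from dranet.simulate import ModuleSpec, labels_to_classes


def brute_force_connectivity(expr_group, genes):
    """Double-loop mean |Pearson r| oracle."""
    vals = []
    for a, b in itertools.combinations(genes, 2):
        x, y = expr_group.loc[a], expr_group.loc[b]
        r = np.corrcoef(x, y)[0, 1]
        vals.append(abs(r))
    return float(np.mean(vals))


def two_group_classes(sens_ids, res_ids):
    labels = pd.Series({**{s: SENSITIVE for s in sens_ids},
                        **{s: RESISTANT for s in res_ids}})
    return labels_to_classes(labels)


class TestFilterModules:
    def test_post_intersection_size_rule(self):
        coll = GeneSetCollection()
        coll.add("big", [f"g{i}" for i in range(35)])       # 29 measured
        coll.add("exact", [f"m{i}" for i in range(30)])     # all measured
        measured = [f"g{i}" for i in range(29)] + [f"m{i}" for i in range(30)]
        kept = filter_modules(coll, measured, min_size=30)
        assert "big" not in kept            # 29 < 30 after intersection
        assert "exact" in kept              # boundary: exactly 30 retained

    def test_empty_collection(self):
        assert len(filter_modules(GeneSetCollection(), ["g"])) == 0


class TestModuleConnectivity:
    def test_perfectly_correlated_pair(self):
        e = pd.DataFrame([[1, 2, 3, 4.0], [2, 4, 6, 8.0]], index=["a", "b"])
        assert module_connectivity(e, ["a", "b"]) == pytest.approx(1.0)

    def test_hand_computed_correlation(self):
        e = pd.DataFrame([[1, 2, 3, 4.0], [2, 1, 4, 3.0]], index=["a", "b"])
        assert module_connectivity(e, ["a", "b"]) == pytest.approx(0.6, abs=1e-12)

    def test_duplicated_genes_full_connectivity(self):
        x = np.array([1.0, 5.0, 2.0, 7.0])
        e = pd.DataFrame([x, x, x], index=["a", "b", "c"])
        assert module_connectivity(e, ["a", "b", "c"]) == pytest.approx(1.0)

    def test_matches_brute_force_double_loop(self, rng):
        e = pd.DataFrame(rng.standard_normal((8, 20)),
                         index=[f"g{i}" for i in range(8)])
        genes = list(e.index)
        assert module_connectivity(e, genes) == pytest.approx(
            brute_force_connectivity(e, genes), abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        flat = pd.DataFrame([[1.0, 1.0, 1.0], [1, 2, 3.0]], index=["a", "b"])
        with pytest.warns(UserWarning):
            with pytest.raises(DegenerateInputError):
                module_connectivity(flat, ["a", "b"])


class TestComputeMDC:
    def test_identical_expression_gives_unity(self, rng):
        block = rng.standard_normal((5, 4))
        e = pd.DataFrame(np.hstack([block, block]),
                         index=[f"g{i}" for i in range(5)],
                         columns=[f"s{i}" for i in range(4)] + [f"r{i}" for i in range(4)])
        classes = two_group_classes([f"s{i}" for i in range(4)],
                                    [f"r{i}" for i in range(4)])
        assert compute_mdc(e, classes, e.index) == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_ratio(self):
        # resistant pair r = 1, sensitive pair r = 0.6 -> MDC = 1/0.6
        sen = np.array([[1, 2, 3, 4.0], [2, 1, 4, 3.0]])
        res = np.array([[1, 2, 3, 4.0], [2, 4, 6, 8.0]])
        e = pd.DataFrame(np.hstack([sen, res]), index=["a", "b"],
                         columns=[f"s{i}" for i in range(4)] + [f"r{i}" for i in range(4)])
        classes = two_group_classes([f"s{i}" for i in range(4)],
                                    [f"r{i}" for i in range(4)])
        assert compute_mdc(e, classes, ["a", "b"]) == pytest.approx(1 / 0.6, abs=1e-12)

    def test_swapping_groups_gives_reciprocal(self, rng):
        for _ in range(50):
            e = pd.DataFrame(rng.standard_normal((6, 12)),
                             index=[f"g{i}" for i in range(6)],
                             columns=[f"c{i}" for i in range(12)])
            c1 = two_group_classes([f"c{i}" for i in range(6)],
                                   [f"c{i}" for i in range(6, 12)])
            c2 = two_group_classes([f"c{i}" for i in range(6, 12)],
                                   [f"c{i}" for i in range(6)])
            m1 = compute_mdc(e, c1, e.index)
            m2 = compute_mdc(e, c2, e.index)
            assert m1 * m2 == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance(self, rng):
        e = pd.DataFrame(rng.standard_normal((4, 10)),
                         index=list("abcd"), columns=[f"c{i}" for i in range(10)])
        classes = two_group_classes([f"c{i}" for i in range(5)],
                                    [f"c{i}" for i in range(5, 10)])
        m1 = compute_mdc(e, classes, e.index)
        e2 = e.copy()
        e2.loc["a"] *= 17.0
        assert compute_mdc(e2, classes, e.index) == pytest.approx(m1, abs=1e-12)


class TestMdcFdr:
    def test_planted_module_significant(self, planted_module_panel):
        expr, classes, coll, _ = planted_module_panel
        r = mdc_fdr(expr, classes, coll["DIFF"], n_perm=50, seed=1,
                    module_name="DIFF")
        assert r.direction == "gain" and r.mdc > 1
        assert r.fdr == 0.0

    def test_fdr_on_permutation_grid(self, planted_module_panel):
        expr, classes, coll, _ = planted_module_panel
        r = mdc_fdr(expr, classes, coll["NULL"], n_perm=50, seed=2)
        grid = {i / 50 for i in range(51)}
        assert r.fdr in grid

    def test_neutral_boundary_convention(self, rng):
        block = rng.standard_normal((4, 5))
        e = pd.DataFrame(np.hstack([block, block]),
                         index=list("abcd"),
                         columns=[f"s{i}" for i in range(5)] + [f"r{i}" for i in range(5)])
        classes = two_group_classes([f"s{i}" for i in range(5)],
                                    [f"r{i}" for i in range(5)])
        r = mdc_fdr(e, classes, list("abcd"), n_perm=10, seed=0)
        assert r.direction == "neutral" and r.fdr == 1.0

    def test_invalid_n_perm(self, planted_module_panel):
        expr, classes, coll, _ = planted_module_panel
        with pytest.raises(ConfigError):
            mdc_fdr(expr, classes, coll["DIFF"], n_perm=0)

    def test_deterministic_given_seed(self, planted_module_panel):
        expr, classes, coll, _ = planted_module_panel
        r1 = mdc_fdr(expr, classes, coll["NULL"], n_perm=20, seed=5)
        r2 = mdc_fdr(expr, classes, coll["NULL"], n_perm=20, seed=5)
        assert r1 == r2


class TestRankAcrossDrugs:
    @staticmethod
    def _results(seed, specs):
        expr, classes, coll, _ = simulate.simulate_differential_modules(
            specs, 60, 60, seed=seed)
        return MDCAnalysis(expr, classes, coll, min_size=30, n_perm=20,
                           seed=seed).fit()

    def test_single_drug_order_preserved(self):
        specs = [ModuleSpec("A", 30, 0.2, 0.7), ModuleSpec("B", 30, 0.5, 0.5)]
        res = self._results(1, specs)
        agg = rank_modules_across_drugs({"d1": res})
        assert agg["module"].tolist() == res.ranked()["module"].tolist()

    def test_consistently_top_module_listed_first(self):
        specs = [ModuleSpec("DIFF", 30, 0.1, 0.8),
                 ModuleSpec("N1", 30, 0.4, 0.4), ModuleSpec("N2", 30, 0.4, 0.4)]
        per_drug = {f"d{i}": self._results(10 + i, specs) for i in range(3)}
        agg = rank_modules_across_drugs(per_drug)
        assert agg.iloc[0]["module"] == "DIFF"

    def test_mismatched_collections_rejected(self):
        r1 = self._results(1, [ModuleSpec("A", 30, 0.2, 0.7)])
        r2 = self._results(2, [ModuleSpec("B", 30, 0.2, 0.7)])
        from dranet.exceptions import InputError
        with pytest.raises(InputError):
            rank_modules_across_drugs({"d1": r1, "d2": r2})
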