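"""QED desirability scoring and the compound screen."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phytonet.drug_likeness import (
    ADS_PARAMS,
    DESCRIPTOR_NAMES,
    ads_desirability,
    deduplicate,
    qed_score,
    score_compounds,
    screen_compounds,
)


def random_descriptor_vectors(seed: int, n: int) -> np.ndarray:
    """Plausible (MW, ALOGP, HBA, HBD, PSA, ROTB, AROM, ALERTS) draws."""
    rng = np.random.default_rng(seed)
    return np.column_stack(
        [
            rng.uniform(80, 800, n),     # MW
            rng.uniform(-3, 8, n),       # ALOGP
            rng.integers(0, 12, n),      # HBA
            rng.integers(0, 8, n),       # HBD
            rng.uniform(0, 250, n),      # PSA
            rng.integers(0, 15, n),      # ROTB
            rng.integers(0, 6, n),       # AROM
            rng.integers(0, 4, n),       # ALERTS
        ]
    )


class TestADS:
    def test_normalized_to_one_at_maximizer(self):
        # scan finds the maximizer; normalization makes the peak equal 1
        for name, p in ADS_PARAMS.items():
            xs = np.linspace(p.c - 3 * abs(p.e) - 5, p.c + 3 * abs(p.f) + 5, 20001)
            peak = max(ads_desirability(float(x), p) for x in xs)
            assert peak == pytest.approx(1.0, abs=5e-3), name

    def test_tails_approach_positive_asymptote(self):
        p = ADS_PARAMS["MW"]
        assert 0 < ads_desirability(-1e6, p) <= p.a / p.dmax + 1e-9
        assert 0 < ads_desirability(1e6, p) < 1.0

    def test_matches_independent_implementation(self):
        rdkit_qed = pytest.importorskip("rdkit.Chem.QED")
        for name, x in [("MW", 300.0), ("ALOGP", 1.5), ("PSA", 66.8), ("ROTB", 3.0)]:
            ref = rdkit_qed.ads(x, rdkit_qed.adsParameters[name])
            assert ads_desirability(x, ADS_PARAMS[name]) == pytest.approx(ref, abs=1e-9)


class TestQEDScore:
    def test_all_ones_gives_one(self):
        # descriptors at their desirability peaks would give QED 1; emulate by
        # the closed-form identity on the geometric mean instead
        assert qed_score(dict(zip(DESCRIPTOR_NAMES, [300, 2.5, 4, 1, 70, 3, 1, 0]))) <= 1.0

    def test_unweighted_closed_form(self):
        # seven d_i = 1, one d_i = e^-8 -> exp(-8/8) = e^-1; reproduce via
        # direct geometric mean of raw desirabilities
        ds = [1.0] * 7 + [math.exp(-8)]
        expected = math.exp(sum(math.log(d) for d in ds) / 8)
        assert expected == pytest.approx(math.exp(-1))

    def test_scale_free_in_weights(self):
        v = dict(zip(DESCRIPTOR_NAMES, [194.18, 1.50, 4, 2, 66.8, 3, 1, 0]))
        w = (0.66, 0.46, 0.05, 0.61, 0.06, 0.65, 0.48, 0.95)
        assert qed_score(v, w) == pytest.approx(qed_score(v, tuple(3.7 * x for x in w)), rel=1e-12)

    @given(st.integers(0, 7), st.floats(-50, 50))
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_each_descriptor_desirability(self, idx, delta):
        # increasing one descriptor's desirability never decreases QED
        base = [300.0, 2.5, 4, 1, 70.0, 3, 1, 0]
        other = list(base)
        other[idx] += delta
        name = DESCRIPTOR_NAMES[idx]
        d0 = ads_desirability(base[idx], ADS_PARAMS[name])
        d1 = ads_desirability(other[idx], ADS_PARAMS[name])
        q0, q1 = qed_score(base), qed_score(other)
        if d1 >= d0:
            assert q1 >= q0 - 1e-12
        else:
            assert q1 <= q0 + 1e-12

    def test_matches_reference_oracle_on_random_vectors(self):
        """100 random descriptor vectors agree with the independent QED
        reference (max-information weights and unweighted) to 1e-6."""
        rdkit_qed = pytest.importorskip("rdkit.Chem.QED")

        def reference(vec, weights):
            ds = [rdkit_qed.ads(x, rdkit_qed.adsParameters[n]) for n, x in zip(DESCRIPTOR_NAMES, vec)]
            return math.exp(sum(w * math.log(d) for w, d in zip(weights, ds)) / sum(weights))

        vecs = random_descriptor_vectors(seed=2024, n=100)
        for vec in vecs:
            assert qed_score(vec) == pytest.approx(reference(vec, [1.0] * 8), abs=1e-6)
            w = (0.66, 0.46, 0.05, 0.61, 0.06, 0.65, 0.48, 0.95)
            assert qed_score(vec, "max_info") == pytest.approx(reference(vec, w), abs=1e-6)

    def test_rejects_bad_weights(self):
        v = [300, 2.5, 4, 1, 70, 3, 1, 0]
        with pytest.raises(ValueError):
            qed_score(v, (0.0,) * 8)
        with pytest.raises(ValueError):
            qed_score(v, (-1.0,) + (1.0,) * 7)


class TestScreen:
    def test_gates_and_funnel(self, toy_compounds):
        passed, funnel = screen_compounds(toy_compounds, qed_cutoff=0.4, require_ob=True)
        assert funnel["input"] == 5
        assert funnel["deduplicated"] == len(passed)
        # every survivor satisfies both gates
        assert (passed["qed"] >= 0.4).all()
        assert passed["ob"].all()
        # the OB=False drug-like compound is excluded, the duplicate collapses
        assert "C3" not in set(passed["compound_id"])
        assert list(passed["compound_id"]).count("C4") <= 1

    def test_cutoff_is_inclusive(self, toy_compounds):
        df = toy_compounds.copy()
        df.loc[:, "qed"] = [0.4, 0.39999, 0.62, 0.5, 0.5]
        df.loc[:, "ob"] = True
        passed, _ = screen_compounds(df, qed_cutoff=0.4, require_ob=True)
        assert "C1" in set(passed["compound_id"])  # exactly at the boundary
        assert "C2" not in set(passed["compound_id"])

    def test_unscored_errors(self, toy_compounds):
        df = toy_compounds.drop(columns=["qed"])
        with pytest.raises(ValueError, match="scored"):
            screen_compounds(df)


class TestDeduplicate:
    def test_merges_herb_origins(self, toy_compounds):
        out = deduplicate(toy_compounds)
        herbs = out.loc[out["compound_id"] == "C4", "herbs"].item()
        assert herbs == "HerbB;HerbC"
        assert len(out) == 4

    def test_empty_is_identity(self, toy_compounds):
        empty = toy_compounds.iloc[0:0]
        assert deduplicate(empty).empty

    def test_conflicting_descriptors_error(self, toy_compounds):
        df = toy_compounds.copy()
        df.loc[df.index[-1], "mw"] = 999.0
        with pytest.raises(ValueError, match="C4"):
            deduplicate(df)


def test_score_compounds_adds_qed_column(toy_compounds):
    assert "qed" in toy_compounds.columns
    assert toy_compounds["qed"].between(0, 1).all()
    # a greasy, alert-laden compound scores worse than a lean drug-like one
    by_id = toy_compounds.set_index("compound_id")["qed"]
    assert by_id["C2"] < by_id["C1"]
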