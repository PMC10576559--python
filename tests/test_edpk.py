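"""EDPK decision strategy: branch logic, invariants, identity reduction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gliomets.edpk import EDPKConfig, EDPKDecision, edpk_decide, edpk_predict
from gliomets.roi import count_lesions, whole_roi
from gliomets.volume import SegMask


def mask_with_lesions(n, shape=(48, 48, 24), size=3, label=2, extra_small=0):
    """n separated cubic lesions of side ``size`` (plus optional tiny blobs)."""
    labels = np.zeros(shape, dtype=np.int16)
    placed = 0
    step = size + 3
    for x in range(1, shape[0] - size, step):
        for y in range(1, shape[1] - size, step):
            if placed >= n:
                break
            labels[x:x + size, y:y + size, 4:4 + size] = label
            placed += 1
        if placed >= n:
            break
    assert placed == n, "grid too small for requested lesion count"
    for k in range(extra_small):
        x = 1 + k * 4
        labels[x:x + 2, 1:3, 18:20] = label  # 8-voxel spurious blobs
    return SegMask(labels=labels, spacing=(1.0, 1.0, 1.0))


class TestDecide:
    def test_low_regime_single_lesion(self):
        decision = edpk_decide(mask_with_lesions(1, size=5), mask_with_lesions(1, size=5))
        assert decision.number == 1
        assert decision.regime == "low"
        assert decision.weights[0] == decision.weights[1]
        assert len(decision.final_mask_set) == 1

    def test_high_regime_many_lesions(self):
        decision = edpk_decide(mask_with_lesions(1, size=5), mask_with_lesions(5, size=5))
        assert decision.number == 5
        assert decision.regime == "high"
        assert len(decision.final_mask_set) == 2
        assert decision.weights == (2.0, 1.0)

    def test_small_components_removed_before_counting(self):
        g = mask_with_lesions(2, size=5, extra_small=3)
        m = mask_with_lesions(2, size=5)
        config = EDPKConfig(min_voxels=50)
        decision = edpk_decide(g, m, config)
        assert decision.l_g == 2  # 8-voxel blobs removed by post-processing
        assert decision.number == 2
        raw_count = count_lesions(whole_roi(g)).lesion_count
        assert raw_count == 5

    def test_counts_depend_on_min_voxels(self):
        g = mask_with_lesions(2, size=5, extra_small=3)
        m = mask_with_lesions(2, size=5)
        decision = edpk_decide(g, m, EDPKConfig(min_voxels=0))
        assert decision.l_g == 5
        assert decision.regime == "high"

    def test_empty_masks_warn(self):
        empty = SegMask(labels=np.zeros((16, 16, 16), dtype=np.int16), spacing=(1, 1, 1))
        with pytest.warns(UserWarning, match="empty"):
            decision = edpk_decide(empty, empty)
        assert decision.regime == "low"
        assert decision.number == 0

    @settings(max_examples=40, deadline=None)
    @given(l_g=st.integers(0, 10), l_m=st.integers(0, 10))
    def test_branch_exhaustive_over_lesion_counts(self, l_g, l_m):
        """Every (L_G, L_M) pair maps to exactly one branch with the
        stated weight/mask-set invariants."""
        g = mask_with_lesions(l_g, size=5)
        m = mask_with_lesions(l_m, size=5)
        config = EDPKConfig(set_number=3, min_voxels=10)
        if l_g == 0 and l_m == 0:
            with pytest.warns(UserWarning):
                decision = edpk_decide(g, m, config)
        else:
            decision = edpk_decide(g, m, config)
        assert decision.l_g == l_g
        assert decision.l_m == l_m
        assert decision.number == max(l_g, l_m)
        low = decision.number < config.set_number
        assert (decision.regime == "low") == low
        assert (decision.weights[0] == decision.weights[1]) == low
        assert (len(decision.final_mask_set) == 1) == low
        if not low:
            assert len(decision.final_mask_set) == 2

    def test_monotone_trigger(self):
        """More lesions never flips a case from high back to low regime."""
        regimes = []
        for n in range(1, 9):
            decision = edpk_decide(mask_with_lesions(n, size=5), mask_with_lesions(1, size=5))
            regimes.append(decision.regime)
        first_high = regimes.index("high")
        assert all(r == "high" for r in regimes[first_high:])

    def test_config_validation(self):
        with pytest.raises(ValueError):
            EDPKConfig(set_number=0)
        with pytest.raises(ValueError):
            EDPKConfig(weight_low=(1.0, 2.0))
        with pytest.raises(ValueError):
            EDPKConfig(high_regime_fusion="nope")

    def test_decision_serialization_reproduces_choice(self):
        decision = edpk_decide(mask_with_lesions(4, size=5), mask_with_lesions(2, size=5))
        payload = decision.to_dict()
        assert payload["number"] == max(payload["L_G"], payload["L_M"])
        assert payload["regime"] == "high"
        assert payload["weights"] == [2.0, 1.0]
        assert payload["n_final_masks"] == 2


class _StubModel:
    """Deterministic probability model keyed on the lesion-number feature."""

    def __init__(self, slope):
        self.slope = slope

    def predict_proba(self, x):
        x = np.asarray(x)
        p1 = 1.0 / (1.0 + np.exp(-self.slope * x[:, -1]))
        return np.column_stack([1 - p1, p1])


def _stub_pipeline(selected):
    from gliomets.ensemble import RSVModel
    from gliomets.featsel import ScalerState

    scaler = ScalerState(
        mean=pd.Series(0.0, index=selected), sd=pd.Series(1.0, index=selected)
    )
    rsv = RSVModel(
        base_kinds=("random_forest", "svm_rbf"),
        base_models=(_StubModel(1.0), _StubModel(0.5)),
        weights=(1.0, 1.0),
    )
    return rsv, scaler


class TestPredict:
    def test_probabilities_valid_and_identity_reduction(self, glioma_case_normalized):
        """With perfect masks (Dice 1) the low-regime EDPK prediction equals
        the plain RSV prediction on the truth ROI."""
        from gliomets.phantom import corrupt_mask, mets_style_mask
        from gliomets.radiomics import FeatureRegistry, FilterConfig, extract_case

        case, t1, fl = glioma_case_normalized
        registry = FeatureRegistry()
        fcfg = FilterConfig(bin_width=0.25)
        selected = registry.case_feature_names()
        rsv, scaler = _stub_pipeline(selected)

        mask_g = corrupt_mask(case.truth_mask, 1.0, seed=0)
        mask_m = corrupt_mask(mets_style_mask(case.truth_mask), 1.0, seed=0)
        record = edpk_predict(
            t1, fl, mask_g, mask_m, rsv, scaler, selected,
            registry=registry, filter_config=fcfg, case_id=case.case_id,
        )
        assert 0.0 <= record.probability <= 1.0
        assert record.decision.regime == "low"

        roi = whole_roi(case.truth_mask)
        vec = extract_case(t1, fl, roi, record.decision.number,
                           registry=registry, config=fcfg)
        direct = rsv.predict_proba(scaler.transform(pd.DataFrame([vec]))[selected])
        assert record.probability == pytest.approx(float(direct[0]), abs=1e-12)

    def test_empty_final_roi_errors(self):
        selected = ["lesion_number"]
        rsv, scaler = _stub_pipeline(selected)
        from gliomets.volume import Volume

        empty = SegMask(labels=np.zeros((16, 16, 16), dtype=np.int16), spacing=(1, 1, 1))
        vol = Volume(data=np.ones((16, 16, 16)), spacing=(1, 1, 1))
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="empty"):
                edpk_predict(vol, vol, empty, empty, rsv, scaler, selected)
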