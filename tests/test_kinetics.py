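import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import pamkit as pk
from pamkit.kinetics import (
    DepletionSeries,
    build_rate_table,
    depletion_ratio,
    estimate_rates,
    fit_exponential_decay,
    vrrt_normalize,
)
from pamkit.reads import PamCountTable
from pamkit.simulate import DEFAULT_TIME_GRID

PAMS = pk.enumerate_pams(4)


def table_from(counts, sample_id="s"):
    return PamCountTable.from_counts(sample_id, counts)


class TestDepletionRatio:
    def test_self_ratio_is_one(self):
        t = table_from({p: 100 for p in PAMS})
        ratios = depletion_ratio(t, t)
        assert all(abs(r - 1.0) < 1e-9 for r in ratios.values())

    def test_half_frequency_gives_half_ratio(self):
        control = table_from({p: 10_000 for p in PAMS})
        counts = {p: 10_000 for p in PAMS}
        counts["TTTA"] = 5_000
        sample = table_from(counts)
        ratios = depletion_ratio(sample, control)
        # large counts: pseudocount and total renormalization are negligible
        assert ratios["TTTA"] == pytest.approx(0.5, abs=2e-3)

    def test_zero_counts_stay_finite(self):
        control = table_from({p: 0 if p == "TTTA" else 100 for p in PAMS})
        sample = table_from({p: 0 if p == "TTTA" else 100 for p in PAMS})
        ratios = depletion_ratio(sample, control, pseudocount=0.5)
        assert np.isfinite(ratios["TTTA"]) and ratios["TTTA"] > 0

    def test_empty_control_rejected(self):
        sample = table_from({p: 1 for p in PAMS})
        empty = PamCountTable("c", {p: 0 for p in PAMS}, total_reads_used=0)
        with pytest.raises(ValueError):
            depletion_ratio(sample, empty)


class TestVrrtNormalize:
    def test_divides_by_vrrt_median(self):
        ratios = {p: 0.8 if pk.iupac_match("VRRT", p) else 0.4 for p in PAMS}
        out = vrrt_normalize(ratios)
        assert out["TTTA"] == pytest.approx(0.5)
        assert out["AGGT"] == pytest.approx(1.0)

    def test_identity_when_median_is_one(self):
        ratios = {p: 1.0 for p in PAMS}
        assert vrrt_normalize(ratios) == ratios

    def test_vrrt_median_is_one_after_normalization(self):
        rng = np.random.default_rng(0)
        ratios = {p: float(rng.uniform(0.1, 2.0)) for p in PAMS}
        out = vrrt_normalize(ratios)
        vals = [out[p] for p in pk.vrrt_pams()]
        assert np.median(vals) == pytest.approx(1.0)

    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_scale_equivariance(self, c):
        rng = np.random.default_rng(1)
        ratios = {p: float(rng.uniform(0.1, 2.0)) for p in PAMS}
        base = vrrt_normalize(ratios)
        scaled = vrrt_normalize({p: c * v for p, v in ratios.items()})
        assert all(scaled[p] == pytest.approx(base[p], rel=1e-9) for p in PAMS)

    def test_degenerate_median_rejected(self):
        ratios = {p: 0.0 for p in PAMS}
        with pytest.raises(ValueError, match="VRRT median"):
            vrrt_normalize(ratios)


class TestFitExponentialDecay:
    @pytest.mark.parametrize("k", [0.0, 0.05, 0.5, 2.0])
    @pytest.mark.parametrize("a", [0.6, 1.0, 1.8])
    def test_noiseless_recovery(self, k, a):
        t = DEFAULT_TIME_GRID
        y = tuple(a * np.exp(-k * np.array(t)))
        est = fit_exponential_decay(DepletionSeries("TTTA", t, y))
        assert est.converged
        assert abs(est.k - k) < 1e-6
        assert abs(est.amplitude - a) < 1e-6

    def test_flat_series_gives_zero_rate(self):
        est = fit_exponential_decay(
            DepletionSeries("AGGT", DEFAULT_TIME_GRID, (1.0,) * 9)
        )
        assert est.k == pytest.approx(0.0, abs=1e-8)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential_decay(DepletionSeries("TTTA", (0.0, 1.0), (1.0, 0.5)))

    def test_requires_t0(self):
        with pytest.raises(ValueError, match="t=0"):
            fit_exponential_decay(
                DepletionSeries("TTTA", (1.0, 2.0, 4.0), (0.5, 0.3, 0.1))
            )

    def test_series_validation(self):
        with pytest.raises(ValueError):
            DepletionSeries("TTTA", (0.0, 2.0, 1.0), (1.0, 0.5, 0.2))
        with pytest.raises(ValueError):
            DepletionSeries("TTTA", (0.0, 1.0, 2.0), (1.0, -0.5, 0.2))


class TestRateTable:
    def test_all_equal_rates_normalize_to_one(self):
        ests = {
            p: pk.RateEstimate(p, 1.0, 0.4, 0.0, True) for p in PAMS[:10]
        }
        table = build_rate_table(ests)
        assert all(v == pytest.approx(1.0) for v in table.normalized_rate.values())

    def test_max_is_exactly_one_and_unique(self):
        ests = {
            p: pk.RateEstimate(p, 1.0, k, 0.0, True)
            for p, k in zip(PAMS, np.linspace(0.0, 0.5, 256))
        }
        table = build_rate_table(ests)
        values = list(table.normalized_rate.values())
        assert max(values) == 1.0
        assert sum(v == 1.0 for v in values) == 1
        assert all(0 <= v <= 1 for v in values)

    def test_nonconverged_excluded(self):
        ests = {p: pk.RateEstimate(p, 1.0, 0.5, 0.0, True) for p in PAMS[:5]}
        ests["TTTT"] = pk.RateEstimate("TTTT", float("nan"), float("nan"), 0.0, False)
        table = build_rate_table(ests)
        assert "TTTT" not in table.normalized_rate

    def test_all_nonconverged_rejected(self):
        ests = {"AAAA": pk.RateEstimate("AAAA", 1.0, 0.1, 0.0, False)}
        with pytest.raises(ValueError):
            build_rate_table(ests)

    def test_matrix_layout(self):
        ests = {p: pk.RateEstimate(p, 1.0, 0.1, 0.0, True) for p in PAMS}
        ests["TTTA"] = pk.RateEstimate("TTTA", 1.0, 0.5, 0.0, True)
        mat = build_rate_table(ests).to_matrix()
        assert mat.shape == (16, 16)
        assert mat.loc["TT", "TA"] == 1.0
        assert mat.to_numpy().max() == 1.0


class TestEndToEnd:
    def test_stringent_top3_are_tttv(self, small_run):
        control = pk.count_pams(small_run.control.iter_reads(), small_run.anchor)
        samples = {
            t: pk.count_pams(s.iter_reads(), small_run.anchor)
            for t, s in small_run.samples.items()
        }
        table = estimate_rates(samples, control)
        top3 = pk.rank_pams(table, 3)
        assert all(pk.classify_pam(p) == "TTTV" for p in top3)
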