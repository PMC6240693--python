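"""Tests of the frozen-fraction → background correction → Vali-equation
estimation chain, detection limits, exact binomial intervals, dilution
merging and the three-replicate quality filter."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dropfreeze import (
    DropletSpec,
    PlateAssay,
    SpectrumComponent,
    SpectrumModel,
    TemperatureProtocol,
    binomial_ci,
    compute_frozen_fraction,
    correct_background,
    detection_limits,
    estimate_spectrum,
    inp_per_cell,
    merge_dilutions,
    replicate_filter,
    simulate_plate,
)
from dropfreeze.assay import (
    FLAG_BELOW_DETECTION,
    FLAG_NEGATIVE_REMOVED,
    FLAG_OK,
    FLAG_SATURATED,
    FrozenFractionCurve,
)
from dropfreeze.simulate import substream_seed


def plate(protocol, counts, n_wells=16, treatment="untreated", **kw):
    droplet = kw.pop("droplet", DropletSpec(volume_ul=20, cells_per_ul=100))
    return PlateAssay(
        sample_id=kw.pop("sample_id", "S"),
        treatment=treatment,
        replicate_id=kw.pop("replicate_id", "r1"),
        droplet=droplet,
        protocol=protocol,
        frozen_counts=tuple(counts),
        n_wells=n_wells,
    )


# ---------------------------------------------------------------- protocol


def test_protocol_rejects_bad_grids():
    with pytest.raises(ValueError):
        TemperatureProtocol((-2.0, -1.0))  # increasing
    with pytest.raises(ValueError):
        TemperatureProtocol((2.0, -4.0))  # above zero
    with pytest.raises(ValueError):
        TemperatureProtocol((-2.0, -8.0))  # 6 °C gap
    with pytest.raises(ValueError):
        TemperatureProtocol((-2.0, -4.0), hold_minutes=0)
    wide = TemperatureProtocol((-2.0, -8.0), max_step=6.0)  # configurable
    assert len(wide) == 2


# --------------------------------------------------------- frozen fraction


def test_frozen_fraction_examples(protocol):
    n = len(protocol)
    assert compute_frozen_fraction(plate(protocol, [0] * n)).fractions == (0.0,) * n
    idx = protocol.setpoints.index(-24.0)
    counts = [0] * n
    for i in range(idx, n):
        counts[i] = 8
    curve = compute_frozen_fraction(plate(protocol, counts))
    assert curve.fractions[idx] == 0.5
    full = compute_frozen_fraction(plate(protocol, [16] * n))
    assert full.fractions == (1.0,) * n


def test_malformed_counts_name_the_setpoint(protocol):
    n = len(protocol)
    with pytest.raises(ValueError, match="-4"):
        plate(protocol, [0, 20] + [20] * (n - 2))  # exceeds n_wells at -4 °C
    with pytest.raises(ValueError, match="cumulative"):
        plate(protocol, [5, 3] + [5] * (n - 2))


# ----------------------------------------------------- background correction


def test_background_identity_and_arithmetic(protocol):
    n = len(protocol)
    sample = compute_frozen_fraction(plate(protocol, range(0, n)))
    zero = FrozenFractionCurve(protocol, (0.0,) * n, 16, "control")
    corrected = correct_background(sample, zero)
    assert corrected.values == sample.fractions
    assert not any(corrected.excluded)

    s = FrozenFractionCurve(protocol, (0.5,) * n, 16)
    c = FrozenFractionCurve(protocol, (0.1,) * n, 16, "control")
    assert correct_background(s, c).values == pytest.approx((0.4,) * n)


def test_negative_corrected_fraction_is_flagged(protocol):
    n = len(protocol)
    s = FrozenFractionCurve(protocol, (0.1,) * n, 16)
    c = FrozenFractionCurve(protocol, (0.2,) * n, 16, "control")
    corrected = correct_background(s, c)
    assert all(corrected.excluded)


def test_mismatched_protocols_raise():
    p1 = TemperatureProtocol((-2.0, -4.0))
    p2 = TemperatureProtocol((-3.0, -5.0))
    s = FrozenFractionCurve(p1, (0.0, 0.5), 16)
    c = FrozenFractionCurve(p2, (0.0, 0.0), 16, "control")
    with pytest.raises(ValueError):
        correct_background(s, c)


# ------------------------------------------------------------ Vali equation


def test_inp_per_cell_closed_forms():
    d = DropletSpec(volume_ul=20, cells_per_ul=100)
    assert inp_per_cell(0.0, d) == 0.0
    # ff = 1 - e^-1 makes the log term exactly 1: N = 1 / (c*V) = 1/2000
    assert inp_per_cell(1 - math.exp(-1), d) == pytest.approx(5e-4, rel=1e-12)
    unit = DropletSpec(volume_ul=1, cells_per_ul=1)
    assert inp_per_cell(0.5, unit) == pytest.approx(math.log(2), rel=1e-12)


def test_inp_per_cell_domain_errors():
    d = DropletSpec(volume_ul=20, cells_per_ul=100)
    with pytest.raises(ValueError, match="saturated"):
        inp_per_cell(1.0, d)
    with pytest.raises(ValueError, match="per-droplet"):
        inp_per_cell(0.5, DropletSpec(volume_ul=20, cells_per_ul=0))


@settings(max_examples=50, derandomize=True, deadline=None)
@given(
    ff=st.floats(min_value=1e-6, max_value=0.999),
    delta=st.floats(min_value=1e-6, max_value=0.3),
    c=st.floats(min_value=0.1, max_value=1e4),
    v=st.floats(min_value=1.0, max_value=50.0),
    factor=st.floats(min_value=1.5, max_value=10.0),
)
def test_vali_monotone_in_ff_and_inverse_in_c_and_v(ff, delta, c, v, factor):
    d = DropletSpec(volume_ul=v, cells_per_ul=c)
    base = inp_per_cell(ff, d)
    ff2 = min(ff + delta, 0.9999)
    assert inp_per_cell(ff2, d) >= base
    assert inp_per_cell(ff, DropletSpec(volume_ul=v, cells_per_ul=c * factor)) == (
        pytest.approx(base / factor, rel=1e-9)
    )
    assert inp_per_cell(ff, DropletSpec(volume_ul=v * factor, cells_per_ul=c)) == (
        pytest.approx(base / factor, rel=1e-9)
    )


# --------------------------------------------------------- detection limits


def test_detection_limit_values():
    d = DropletSpec(volume_ul=20, cells_per_ul=100)  # cV = 2000
    lower, upper = detection_limits(32, d)
    assert lower == pytest.approx(-math.log(31 / 32) / 2000, rel=1e-12)
    assert lower == pytest.approx(1.588e-5, rel=1e-3)
    assert lower < upper
    unit = DropletSpec(volume_ul=1, cells_per_ul=1)
    assert detection_limits(16, unit)[0] == pytest.approx(-math.log(15 / 16), rel=1e-12)


def test_lower_limit_decreases_with_more_wells():
    d = DropletSpec(volume_ul=20, cells_per_ul=100)
    limits = [detection_limits(n, d)[0] for n in (8, 16, 32, 64)]
    assert limits == sorted(limits, reverse=True)


# --------------------------------------------------------------- binomial CI


def binomial_ci_bisect(k, n, level):
    """Oracle: invert the binomial tail probabilities by bisection."""
    from scipy.stats import binom

    alpha = 1 - level

    def solve(f, lo, hi):
        for _ in range(200):
            mid = (lo + hi) / 2
            if f(mid):
                hi = mid
            else:
                lo = mid
        return (lo + hi) / 2

    low = 0.0 if k == 0 else solve(lambda p: binom.sf(k - 1, n, p) > alpha / 2, 0, 1)
    high = 1.0 if k == n else solve(lambda p: binom.cdf(k, n, p) < alpha / 2, 0, 1)
    return low, high


def test_clopper_pearson_boundaries_and_oracle():
    assert binomial_ci(0, 16)[0] == 0.0
    assert binomial_ci(16, 16)[1] == 1.0
    low, high = binomial_ci(8, 16, 0.95)
    olow, ohigh = binomial_ci_bisect(8, 16, 0.95)
    assert low == pytest.approx(olow, abs=1e-6)
    assert high == pytest.approx(ohigh, abs=1e-6)


def test_clopper_pearson_coverage_at_least_nominal():
    rng = np.random.default_rng(17)
    n, p, n_sim = 24, 0.3, 2000
    hits = 0
    for k in rng.binomial(n, p, size=n_sim):
        low, high = binomial_ci(int(k), n, 0.95)
        hits += low <= p <= high
    mc_err = np.sqrt(0.95 * 0.05 / n_sim)
    assert hits / n_sim >= 0.95 - 3 * mc_err


# ---------------------------------------------------------- spectrum chain


def test_identical_sample_and_control_give_zero_spectrum(protocol):
    n = len(protocol)
    counts = [min(i, 14) for i in range(0, 2 * n, 2)]
    sample = plate(protocol, counts)
    control = plate(protocol, counts, treatment="control",
                    droplet=DropletSpec(volume_ul=20))
    spec = estimate_spectrum(sample, control)
    for v, fl in zip(spec.values, spec.flags):
        assert v == 0.0
        assert fl == FLAG_BELOW_DETECTION


def test_spectrum_flags_negative_saturated_and_ok():
    proto = TemperatureProtocol((-4.0, -6.0, -8.0))
    sample = plate(proto, [0, 8, 16])
    control = plate(proto, [1, 1, 1], treatment="control",
                    droplet=DropletSpec(volume_ul=20))
    spec = estimate_spectrum(sample, control)
    assert spec.flags == (FLAG_NEGATIVE_REMOVED, FLAG_OK, FLAG_SATURATED)
    assert math.isnan(spec.values[0])
    # saturated upper confidence bound is unbounded
    assert spec.ci_high[2] == math.inf
    assert spec.values[2] <= spec.ci_high[2]


def test_per_droplet_mode_for_cell_free_plates():
    proto = TemperatureProtocol((-4.0, -6.0))
    filt = plate(proto, [0, 8], treatment="filtrate",
                 droplet=DropletSpec(volume_ul=20, cells_per_ul=0))
    spec = estimate_spectrum(filt)
    assert spec.unit == "per_droplet"
    assert spec.values[1] == pytest.approx(-math.log(0.5) / 20.0)


def test_estimator_converges_to_constant_hazard_truth():
    """Plates from a constant hazard at one setpoint: the Vali estimate's
    mean over many plates approaches lambda/(cV) within Monte Carlo error."""
    lam = 0.693
    proto = TemperatureProtocol((-10.0,))
    droplet = DropletSpec(volume_ul=1.0, cells_per_ul=1.0)
    model = SpectrumModel(
        (SpectrumComponent("proteinaceous", "particulate", -10.0, lam, 0.0),)
    )
    estimates = []
    for i in range(200):
        p = simulate_plate(model, droplet, proto, 32, substream_seed(99, "conv", i))
        estimates.append(estimate_spectrum(p).values[0])
    estimates = np.asarray(estimates)
    se = estimates.std(ddof=1) / np.sqrt(len(estimates))
    assert abs(estimates.mean() - lam) <= 3 * se


# --------------------------------------------------------- merge_dilutions


def two_setpoint_spectra():
    proto = TemperatureProtocol((-10.0, -12.0))
    d1 = DropletSpec(volume_ul=20, cells_per_ul=100, dilution_factor=1)
    d2 = DropletSpec(volume_ul=20, cells_per_ul=10, dilution_factor=10)
    from conftest import make_spectrum

    s1 = make_spectrum(proto, (2e-3, 4e-3), (FLAG_OK, FLAG_SATURATED), droplet=d1)
    s2 = make_spectrum(proto, (4e-3, 5e-3), (FLAG_OK, FLAG_OK), droplet=d2)
    return s1, s2


def test_merge_single_spectrum_is_identity():
    s1, _ = two_setpoint_spectra()
    assert merge_dilutions([s1]) is s1


def test_merge_takes_mean_of_ok_and_excludes_saturated():
    s1, s2 = two_setpoint_spectra()
    merged = merge_dilutions([s1, s2])
    assert merged.values[0] == pytest.approx(3e-3)  # mean of 2e-3 and 4e-3
    assert merged.values[1] == pytest.approx(5e-3)  # saturated dilution excluded
    assert merged.flags == (FLAG_OK, FLAG_OK)


def test_merge_is_permutation_invariant():
    s1, s2 = two_setpoint_spectra()
    a = merge_dilutions([s1, s2])
    b = merge_dilutions([s2, s1])
    assert a.values == b.values and a.flags == b.flags


def test_merge_empty_input_rejected():
    with pytest.raises(ValueError):
        merge_dilutions([])


# -------------------------------------------------------- replicate_filter


def test_replicate_filter_rules(protocol):
    from conftest import make_spectrum

    proto = TemperatureProtocol((-10.0, -12.0))
    active = lambda rid: make_spectrum(
        proto, (2e-3, 3e-3), (FLAG_OK, FLAG_OK), replicate_id=rid
    )
    silent = make_spectrum(
        proto, (0.0, 0.0), (FLAG_BELOW_DETECTION, FLAG_BELOW_DETECTION),
        replicate_id="r3",
    )
    kept = replicate_filter([active("r1"), active("r2"), active("r3")])
    assert kept.retained
    dropped = replicate_filter([active("r1"), active("r2"), silent])
    assert not dropped.retained and "r3" in dropped.reason
    all_silent = replicate_filter([silent, silent, silent])
    assert not all_silent.retained
    with pytest.raises(ValueError, match="3"):
        replicate_filter([active("r1"), active("r2")])
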