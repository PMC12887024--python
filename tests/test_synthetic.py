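"""Generator contracts: grids, truncated draws, coupling, determinism."""

import numpy as np
import pytest

import palmspec as ps
from palmspec.synthetic import _pseudo_voigt, default_market_profiles, default_peaks


# ------------------------------------------------------------------- grid


def test_default_grid_shape_and_span():
    g = ps.make_wavenumber_grid(1024, 500, 2000)
    assert g.size == 1024
    assert g[0] == 500 and g[-1] == 2000
    assert np.allclose(np.diff(g), np.diff(g)[0])


@pytest.mark.parametrize(
    "n, lo, hi, check",
    [
        (2, 0, 1, lambda g: np.array_equal(g, [0.0, 1.0])),
        (5, 500, 2000, lambda g: np.allclose(np.diff(g), 375.0)),
    ],
)
def test_grid_examples(n, lo, hi, check):
    assert check(ps.make_wavenumber_grid(n, lo, hi))


@pytest.mark.parametrize("n, lo, hi", [(1, 0, 1), (0, 0, 1), (10, 5, 5), (10, 9, 2)])
def test_grid_invalid_arguments(n, lo, hi):
    with pytest.raises(ValueError):
        ps.make_wavenumber_grid(n, lo, hi)


# ------------------------------------------------------------ references


def test_truncated_draws_match_market_statistics(rng):
    """10,000 draws: mean within 3 SE of the profile mean, all inside range."""
    profiles = {p.name: p for p in default_market_profiles()}

    agb = profiles["AGB"]
    pv = np.array([ps.draw_reference_values(agb, rng).pv for _ in range(10_000)])
    assert pv.min() >= agb.pv_min and pv.max() <= agb.pv_max
    # truncation shifts the mean slightly; allow 3 SE around the nominal 6.79
    se = agb.pv_sd / np.sqrt(10_000)
    assert abs(pv.mean() - 6.79) < 3 * se + 0.25  # 0.25 = truncation bias allowance

    mak = profiles["MAK"]
    iv = np.array([ps.draw_reference_values(mak, rng).iv for _ in range(10_000)])
    assert iv.min() >= 45.67 and iv.max() <= 48.69
    assert abs(iv.mean() - 47.24) < 3 * mak.iv_sd / np.sqrt(10_000) + 0.25


def test_degenerate_sd_limit(rng):
    profile = ps.MarketProfile(
        name="X", pv_mean=7.0, pv_sd=1e-12, pv_min=6.0, pv_max=8.0,
        iv_mean=46.0, iv_sd=1e-12, iv_min=45.0, iv_max=47.0,
    )
    for _ in range(20):
        refs = ps.draw_reference_values(profile, rng)
        assert refs.pv == pytest.approx(7.0, abs=1e-9)
        assert refs.iv == pytest.approx(46.0, abs=1e-9)


def test_correlated_draws(rng):
    agb = default_market_profiles()[0]
    vals = [ps.draw_reference_values(agb, rng, correlation=-0.8) for _ in range(4000)]
    r = np.corrcoef([v.pv for v in vals], [v.iv for v in vals])[0, 1]
    assert r < -0.5  # strongly negative, attenuated only by truncation


def test_profile_validation():
    with pytest.raises(ValueError):
        ps.MarketProfile("B", pv_mean=5.0, pv_sd=1.0, pv_min=6.0, pv_max=8.0,
                         iv_mean=46.0, iv_sd=1.0, iv_min=45.0, iv_max=47.0)


# --------------------------------------------------------------- spectra


def _config_noise_free(**kw):
    return ps.GeneratorConfig(noise_sd=0.0, baseline_jitter=0.0, **kw)


def test_render_decoupled_limit(tiny_grid, rng):
    """With all couplings zero the spectrum is independent of PV/IV."""
    peaks = tuple(
        ps.PeakSpec(center=p.center, width=p.width, base_amplitude=p.base_amplitude)
        for p in default_peaks()
    )
    cfg = _config_noise_free(peaks=peaks)
    a = ps.render_spectrum(tiny_grid, ps.ReferenceValues(pv=5.0, iv=42.0), cfg, rng)
    b = ps.render_spectrum(tiny_grid, ps.ReferenceValues(pv=11.0, iv=48.0), cfg, rng)
    assert np.array_equal(a, b)


def test_coupled_peak_is_affine_in_pv(tiny_grid, rng):
    """Intensity at the carbonyl channel is affine in PV with slope = coupling."""
    pk = ps.PeakSpec(center=1748.0, width=16.0, base_amplitude=0.1, pv_coupling=0.05)
    cfg = _config_noise_free(peaks=(pk,), baseline_poly_coeffs=(0.0,),
                             fluorescence_amplitude=0.0)
    ch = int(np.argmin(np.abs(tiny_grid - 1748.0)))
    shape = _pseudo_voigt(tiny_grid[ch : ch + 1], 1748.0, 16.0, 0.7)[0]
    pvs = np.array([5.0, 7.0, 11.0])
    vals = np.array([
        ps.render_spectrum(tiny_grid, ps.ReferenceValues(pv=v, iv=46.0), cfg, rng)[ch]
        for v in pvs
    ])
    slopes = np.diff(vals) / np.diff(pvs)
    assert np.allclose(slopes, 0.05 * shape, rtol=1e-12)
    assert np.all(np.diff(vals) > 0)  # strictly increasing in PV


def test_replicate_averaging_reduces_noise_variance(rng):
    """Per-channel variance of the averaged spectrum ~ noise_sd^2 / 3."""
    grid = ps.make_wavenumber_grid(8, 500, 2000)
    cfg = ps.GeneratorConfig(noise_sd=0.05, n_replicates=3, baseline_jitter=0.0)
    refs = ps.ReferenceValues(pv=7.0, iv=46.0)
    draws = np.array([ps.render_spectrum(grid, refs, cfg, rng) for _ in range(1500)])
    var = draws.var(axis=0).mean()
    assert var == pytest.approx(0.05**2 / 3, rel=0.15)


def test_negative_amplitude_clips_with_warning(tiny_grid, rng):
    pk = ps.PeakSpec(center=1748.0, width=16.0, base_amplitude=0.0, pv_coupling=-0.1)
    cfg = _config_noise_free(peaks=(pk,), baseline_poly_coeffs=(0.0,),
                             fluorescence_amplitude=0.0)
    with pytest.warns(UserWarning, match="clipped"):
        out = ps.render_spectrum(tiny_grid, ps.ReferenceValues(pv=5.0, iv=46.0), cfg, rng)
    assert np.all(out == 0)


# ---------------------------------------------------------------- dataset


def test_dataset_counts_and_labels(tiny_grid):
    ds = ps.simulate_dataset(ps.GeneratorConfig(n_per_market=40, seed=1), grid=tiny_grid)
    assert ds.n_samples == 200  # 40 x 5 markets
    counts = {m: ds.markets.count(m) for m in set(ds.markets)}
    assert counts == {"AGB": 40, "DOM": 40, "KAN": 40, "MAD": 40, "MAK": 40}

    tiny = ps.simulate_dataset(ps.GeneratorConfig(n_per_market=1, seed=1), grid=tiny_grid)
    assert tiny.n_samples == 5 and sorted(set(tiny.markets)) == ["AGB", "DOM", "KAN", "MAD", "MAK"]


def test_dataset_determinism(tiny_grid):
    a = ps.simulate_dataset(ps.GeneratorConfig(n_per_market=3, seed=42), grid=tiny_grid)
    b = ps.simulate_dataset(ps.GeneratorConfig(n_per_market=3, seed=42), grid=tiny_grid)
    assert np.array_equal(a.intensities, b.intensities)
    assert a.reference.equals(b.reference)
    c = ps.simulate_dataset(ps.GeneratorConfig(n_per_market=3, seed=43), grid=tiny_grid)
    assert not np.array_equal(a.intensities, c.intensities)


def test_reference_range_safety(small_dataset):
    profiles = {p.name: p for p in default_market_profiles()}
    for sid, market in zip(small_dataset.sample_ids, small_dataset.markets):
        pr = profiles[market]
        row = small_dataset.reference.loc[sid]
        assert pr.pv_min <= row.pv <= pr.pv_max
        assert pr.iv_min <= row.iv <= pr.iv_max


def test_empty_profiles_invalid():
    with pytest.raises(ValueError):
        ps.GeneratorConfig(profiles=())


def test_csv_round_trip(tmp_path, tiny_grid):
    ds = ps.simulate_dataset(ps.GeneratorConfig(n_per_market=2, seed=9), grid=tiny_grid)
    ds.to_csv(tmp_path)
    assert (tmp_path / "spectra.csv").exists() and (tmp_path / "manifest.json").exists()
    back = ps.SpectralDataset.from_csv(tmp_path)
    assert back.sample_ids == ds.sample_ids
    assert np.allclose(back.intensities, ds.intensities)
    assert np.allclose(back.wavenumbers, ds.wavenumbers)
    assert np.allclose(back.reference.values, ds.reference.values)
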