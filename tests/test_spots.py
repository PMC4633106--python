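"""Tests of fixed-width Gaussian spot fitting and amplitude histograms."""

import itertools

import numpy as np
import pytest

from thinfil import (AmplitudeHistogram, fit_frame, fit_movie, movie_histogram,
                     rescale_histograms, rms_error_distribution, SpotFit)

SIGMA = 2.0


def gauss(x, c, a, s=SIGMA):
    return a * np.exp(-0.5 * ((x - c) / s) ** 2)


def test_exact_recovery_single_spot():
    x = np.arange(40, dtype=float)
    profile = gauss(x, 17.3, 118.0)
    fit = fit_frame(profile, SIGMA, min_amplitude=10.0)
    assert fit.n_spots == 1
    assert fit.amplitudes[0] == pytest.approx(118.0, abs=1e-6)
    assert fit.centers[0] == pytest.approx(17.3, abs=1e-3)
    assert fit.rms < 1e-6 * 118.0


def test_exact_recovery_two_separated_spots():
    x = np.arange(50, dtype=float)
    profile = gauss(x, 15.0, 45.0) + gauss(x, 27.0, 90.0)
    fit = fit_frame(profile, SIGMA, min_amplitude=10.0)
    assert fit.n_spots == 2
    assert fit.amplitudes == pytest.approx([45.0, 90.0], abs=1e-6)
    assert fit.centers == pytest.approx([15.0, 27.0], abs=1e-3)
    assert fit.rms < 1e-6 * 90.0


def _brute_force_best_gaussians(profile, x, n_spots, sigma, grid_step=0.05):
    """Independent oracle: grid search over centres with the amplitude(s)
    solved exactly by linear least squares at each grid point."""
    grids = [np.arange(x[0], x[-1] + 1e-9, grid_step)] * n_spots
    best = (np.inf, None, None)
    for centers in itertools.product(*grids):
        if n_spots == 2 and centers[1] <= centers[0]:
            continue
        G = np.stack([np.exp(-0.5 * ((x - c) / sigma) ** 2) for c in centers], axis=1)
        amps, *_ = np.linalg.lstsq(G, profile, rcond=None)
        if np.any(amps < 0):
            continue
        sse = float(((G @ amps - profile) ** 2).sum())
        if sse < best[0]:
            best = (sse, np.array(centers), amps)
    return best


def test_unresolved_pair_merges_like_best_single_gaussian():
    """Two equal spots 1 px apart are fitted as one merged spot whose
    amplitude matches the brute-force best single-Gaussian fit."""
    x = np.arange(25, dtype=float)
    A = 60.0
    profile = gauss(x, 11.5, A) + gauss(x, 12.5, A)
    fit = fit_frame(profile, SIGMA, min_amplitude=10.0)
    assert fit.n_spots == 1
    sse, centers, amps = _brute_force_best_gaussians(profile, x, 1, SIGMA)
    assert fit.amplitudes[0] == pytest.approx(amps[0], abs=0.05)
    assert fit.centers[0] == pytest.approx(centers[0], abs=0.05)
    # the merged amplitude is near the summed overlap at the midpoint
    assert fit.amplitudes[0] == pytest.approx(2 * A * np.exp(-0.5 * (0.5 / SIGMA) ** 2),
                                              rel=0.02)


def test_fit_matches_brute_force_oracle_two_spots():
    x = np.arange(25, dtype=float)
    profile = gauss(x, 8.2, 50.0) + gauss(x, 16.9, 80.0)
    fit = fit_frame(profile, SIGMA, min_amplitude=10.0)
    sse, centers, amps = _brute_force_best_gaussians(profile, x, 2, SIGMA)
    assert fit.n_spots == 2
    assert fit.centers == pytest.approx(centers, abs=0.06)
    assert fit.amplitudes == pytest.approx(amps, abs=0.5)


def test_threshold_monotonicity():
    """Raising the detection threshold never increases the spot count."""
    rng = np.random.default_rng(8)
    x = np.arange(48, dtype=float)
    profile = (gauss(x, 10.0, 30.0) + gauss(x, 25.0, 60.0) + gauss(x, 38.0, 15.0)
               + rng.normal(0, 3.0, x.size))
    counts = [fit_frame(profile, SIGMA, thr).n_spots
              for thr in (5.0, 12.0, 20.0, 40.0, 70.0)]
    assert counts == sorted(counts, reverse=True)


def test_rejects_bad_profiles():
    with pytest.raises(ValueError):
        fit_frame(np.array([1.0, np.nan, 2.0] * 10), SIGMA, 1.0)
    with pytest.raises(ValueError):
        fit_frame(np.ones(5), SIGMA, 1.0)  # shorter than 5 PSF widths


def _fits_from_amplitudes(amp_lists):
    return [SpotFit(centers=np.arange(len(a), dtype=float) * 10 + 10,
                    amplitudes=np.asarray(a, dtype=float), sigma_px=SIGMA, rms=0.0)
            for a in amp_lists]


def test_histogram_binning_and_normalization():
    fits = _fits_from_amplitudes([[45.0], [45.0], [90.0], [45.0]])
    hist = movie_histogram(fits, bin_width=10.0)
    k = np.searchsorted(hist.edges, 45.0, side="right") - 1
    assert hist.counts[k] == 3
    # np.histogram bins are half-open [left, right); 45.0 sits exactly on
    # an edge with centres on multiples of the bin width
    assert hist.edges[k] <= 45.0 < hist.edges[k + 1]
    assert hist.mode_bin() == (hist.edges[k], hist.edges[k + 1])
    norm = movie_histogram(fits, bin_width=10.0, normalized=True)
    assert norm.counts.max() == 1.0


def test_empty_fit_list_gives_empty_histogram():
    hist = movie_histogram([], bin_width=10.0)
    assert hist.counts.size == 0
    hist2 = movie_histogram(_fits_from_amplitudes([[]]), bin_width=10.0)
    assert hist2.counts.size == 0


def test_rescale_histograms_arithmetic():
    h = AmplitudeHistogram(edges=np.array([0.0, 59.0, 118.0, 177.0]),
                           counts=np.array([1.0, 5.0, 2.0]), frame_rate_hz=3.8)
    (hs,) = rescale_histograms([h], e=450.0)
    assert hs.edges[2] == pytest.approx(118.0 * 3.8 / 450.0)
    assert hs.edges[2] == pytest.approx(0.99644, abs=1e-4)
    assert np.array_equal(hs.counts, h.counts)


def test_rescale_requires_frame_rate():
    h = AmplitudeHistogram(edges=np.array([0.0, 1.0]), counts=np.array([1.0]))
    with pytest.raises(ValueError):
        rescale_histograms([h], e=450.0)


def test_identical_amplitudes_collapse_across_frame_rates():
    """The same underlying scaled amplitudes recorded at 10 and 3.8 Hz give
    identical histograms after rescaling."""
    scaled = np.array([0.8, 1.0, 1.1, 2.0])
    hists = []
    for f in (10.0, 3.8):
        unit = 450.0 / f
        fits = _fits_from_amplitudes([[a * unit] for a in scaled])
        hists.append(movie_histogram(fits, bin_width=0.25 * unit, frame_rate_hz=f))
    a, b = rescale_histograms(hists, e=450.0)
    assert np.allclose(a.edges, b.edges)
    assert np.array_equal(a.counts, b.counts)


def test_noise_free_movie_has_zero_rms():
    x = np.arange(30, dtype=float)
    frames = np.stack([gauss(x, 9.0, 50.0), gauss(x, 20.0, 75.0), np.zeros(30)])
    fits = fit_movie(frames, SIGMA, min_amplitude=10.0)
    rms = rms_error_distribution(fits)
    assert rms.shape == (3,)
    assert np.all(rms < 1e-6 * 75.0)


def test_noise_only_rms_matches_background_sd():
    """For frames of pure Gaussian background, nothing is fitted and the
    per-frame RMS estimates the noise SD."""
    rng = np.random.default_rng(17)
    sd = 11.25  # sigma_N=0.25 in raw units at 10 Hz
    frames = rng.normal(0.0, sd, size=(300, 48))
    fits = fit_movie(frames, SIGMA, min_amplitude=2.5 * sd)
    assert sum(f.n_spots for f in fits) == 0
    rms = rms_error_distribution(fits)
    assert rms.mean() == pytest.approx(sd, rel=0.05)
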