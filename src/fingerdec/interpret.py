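"""Physiological interpretation of trained decoder weights.

Spatial filters (demixing weights W) are not themselves source
topographies; the interpretable quantity is the activation pattern

    A = Kxx . W . Kss^{-1}

where Kxx is the sensor-space covariance and Kss the covariance of the
latent sources S_hat = W^T X (Haufe forward-model reconstruction).  This
module also produces, per latent component, the trial-averaged time
course with its Morlet-wavelet time-frequency power map, and the spectral
triplet (input PSD, squared-magnitude FIR response, output PSD) that
makes the temporal layer directly readable as a filter bank.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .data import EpochSet
from .decoder import LFCNN

#: default wavelet grid: 5-40 Hz (below 5 Hz a >=3-cycle wavelet no longer
#: fits inside a 1-s epoch), n_cycles = f/2 bounded below by 3
DEFAULT_TFR_FREQS = np.arange(5.0, 41.0, 1.0)


@dataclass
class ActivationPatternSet:
    """Reconstructed patterns and the covariances behind them.

    ``A`` is the raw solution of the reconstruction equation; ``A_normed``
    applies the reporting convention (unit-norm columns, sign flipped so
    the maximum-magnitude coefficient is positive) — the equation leaves
    per-component sign and scale undetermined.
    """

    A: np.ndarray           # (n, k) raw patterns
    A_normed: np.ndarray    # (n, k) unit-norm, sign-aligned
    Kxx: np.ndarray         # (n, n)
    Kss: np.ndarray         # (k, k)
    data_scope: str = ""


@dataclass
class SpectralProfile:
    freqs: np.ndarray          # common Hz grid
    input_psd: np.ndarray      # (k, n_freqs) mean PSD of spatial-layer output
    filter_response: np.ndarray  # (k, n_freqs) |FIR DFT|^2
    output_psd: np.ndarray     # (k, n_freqs) mean PSD of temporal-layer output


@dataclass
class LatentTFR:
    times: np.ndarray
    freqs: np.ndarray
    mean_source: np.ndarray    # (k, t) trial-averaged temporal-layer output
    power: np.ndarray          # (k, n_freqs, t) mean of single-trial power


def _pooled_cov(data2d: np.ndarray) -> np.ndarray:
    """Covariance over columns of (features x observations), mean removed."""
    centered = data2d - data2d.mean(axis=1, keepdims=True)
    return centered @ centered.T / (data2d.shape[1] - 1)


def activation_patterns(
    W: np.ndarray | LFCNN,
    x: EpochSet | np.ndarray,
    data_scope: str = "",
    ridge: float | None = None,
    max_cond: float = 1e10,
) -> ActivationPatternSet:
    """Reconstruct activation patterns A = Kxx W Kss^{-1}.

    Covariances are pooled over trials and time with the mean removed.
    If Kss is ill-conditioned (condition number above ``max_cond``), a
    ridge of ``1e-6 * trace(Kss)/k`` is added before inversion; if it is
    singular beyond that, an error reports the condition number.
    """
    if isinstance(W, LFCNN):
        W = W.W
    W = np.asarray(W, dtype=float)
    X = x.data if isinstance(x, EpochSet) else np.asarray(x)
    n = W.shape[0]
    flat = np.moveaxis(X, 1, 0).reshape(n, -1)   # channels x (trials*time)
    Kxx = _pooled_cov(flat)
    S = W.T @ flat
    Kss = _pooled_cov(S)

    k = W.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        cond = np.linalg.cond(Kss)
    if ridge is None and not cond <= max_cond:
        ridge = 1e-6 * np.trace(Kss) / k
    Kss_inv_target = Kss + ridge * np.eye(k) if ridge else Kss
    with np.errstate(divide="ignore", invalid="ignore"):
        cond_target = np.linalg.cond(Kss_inv_target)
    if not cond_target <= 1e14:
        raise np.linalg.LinAlgError(
            f"latent covariance singular beyond ridge tolerance "
            f"(condition number {cond:.3g})"
        )
    A = np.linalg.solve(Kss_inv_target.T, (Kxx @ W).T).T

    norms = np.linalg.norm(A, axis=0)
    norms[norms == 0] = 1.0
    A_normed = A / norms
    signs = np.sign(A_normed[np.abs(A_normed).argmax(axis=0), np.arange(k)])
    signs[signs == 0] = 1.0
    A_normed = A_normed * signs
    return ActivationPatternSet(A=A, A_normed=A_normed, Kxx=Kxx, Kss=Kss,
                                data_scope=data_scope)


def average_patterns(sets: list[ActivationPatternSet]) -> np.ndarray:
    """Average normalized patterns across folds after sign alignment to
    the first set (per-component dot-product sign)."""
    ref = sets[0].A_normed
    acc = np.zeros_like(ref)
    for s in sets:
        dots = np.einsum("nk,nk->k", ref, s.A_normed)
        acc += s.A_normed * np.where(dots < 0, -1.0, 1.0)
    avg = acc / len(sets)
    norms = np.linalg.norm(avg, axis=0)
    norms[norms == 0] = 1.0
    return avg / norms


def latent_tfr(
    model: LFCNN,
    x: EpochSet,
    freqs: np.ndarray | None = None,
    n_cycles: np.ndarray | None = None,
) -> LatentTFR:
    """Trial-averaged latent sources and their Morlet TFR power.

    The latent source is the temporal-layer output (spatial projection
    then component-wise FIR).  Power maps average the *single-trial*
    wavelet power, so induced (non-phase-locked) activity survives.
    """
    from mne.time_frequency import tfr_array_morlet

    freqs = DEFAULT_TFR_FREQS if freqs is None else np.asarray(freqs, dtype=float)
    if np.any(freqs >= x.sfreq / 2):
        raise ValueError("requested TFR frequencies reach or exceed Nyquist")
    if n_cycles is None:
        n_cycles = np.maximum(freqs / 2.0, 3.0)
    latent = model.temporal(model.spatial(x.data))
    power = tfr_array_morlet(
        latent, sfreq=x.sfreq, freqs=freqs, n_cycles=n_cycles,
        output="power", zero_mean=True, verbose="error",
    ).mean(axis=0)
    return LatentTFR(times=x.times, freqs=freqs,
                     mean_source=latent.mean(axis=0), power=power)


def save_patterns_h5(path, pats: ActivationPatternSet) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("A", data=pats.A)
        f.create_dataset("A_normed", data=pats.A_normed)
        f.create_dataset("Kxx", data=pats.Kxx)
        f.create_dataset("Kss", data=pats.Kss)
        f.attrs["data_scope"] = pats.data_scope


def save_tfr_h5(path, tfr: LatentTFR) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=tfr.times)
        f.create_dataset("freqs", data=tfr.freqs)
        f.create_dataset("mean_source", data=tfr.mean_source)
        f.create_dataset("power", data=tfr.power)


def plot_topography(pattern: np.ndarray, layout: np.ndarray, path=None,
                    ax=None):
    """Render one spatial pattern on the 2-D sensor layout (cosmetic)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        fig, ax = plt.subplots(figsize=(3, 3))
    else:
        fig = ax.figure
    sc = ax.scatter(layout[:, 0], layout[:, 1], c=pattern, cmap="RdBu_r",
                    s=30, vmin=-np.abs(pattern).max(),
                    vmax=np.abs(pattern).max())
    ax.set_aspect("equal")
    ax.axis("off")
    fig.colorbar(sc, ax=ax, shrink=0.7)
    if path is not None:
        fig.savefig(path, dpi=100, bbox_inches="tight")
        plt.close(fig)
    return ax


def fir_spectra(model: LFCNN, x: EpochSet | np.ndarray) -> SpectralProfile:
    """Input PSD, FIR squared-magnitude response and output PSD per component.

    PSDs are Hann-window periodograms averaged over trials; the filter
    response is the zero-padded DFT of each kernel on the same grid.  The
    temporal layer's additive bias is excluded from the output spectrum
    (it only shifts DC).
    """
    X = x.data if isinstance(x, EpochSet) else np.asarray(x)
    sfreq = x.sfreq if isinstance(x, EpochSet) else 1.0
    if X.shape[-1] < 2:
        raise ValueError("epochs must contain at least 2 samples")
    S = model.spatial(X)
    Y = model.temporal(S, include_bias=False)
    t = X.shape[-1]
    freqs, in_psd = signal.periodogram(S, fs=sfreq, window="hann", axis=-1)
    _, out_psd = signal.periodogram(Y, fs=sfreq, window="hann", axis=-1)
    H = np.abs(np.fft.rfft(model.fir, n=t, axis=1)) ** 2
    return SpectralProfile(
        freqs=freqs,
        input_psd=in_psd.mean(axis=0),
        filter_response=H,
        output_psd=out_psd.mean(axis=0),
    )
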