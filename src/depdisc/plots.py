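"""Optional matplotlib figures: sweep curves, CM spectra, trajectory overlays."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .dep import CMSpectrum
from .circuit import FrequencySweepResult
from .field import FieldMap
from .trajectory import TrajectoryResult


def plot_sweep(sweep: FrequencySweepResult, path: str | Path) -> Path:
    """Transmitter/receiver Vpp versus frequency, resonance peak marked."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(sweep.frequencies / 1e6, sweep.v_tx_pp, label="transmitter")
    ax.plot(sweep.frequencies / 1e6, sweep.v_rx_pp, label="receiver")
    ax.axvline(sweep.resonance_peak / 1e6, ls="--", color="grey", lw=0.8)
    ax.set_xlabel("frequency (MHz)")
    ax.set_ylabel("voltage (Vpp)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_cm_spectrum(spectrum: CMSpectrum, path: str | Path) -> Path:
    """Re/Im of the Clausius–Mossotti factor over frequency (log axis)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.semilogx(spectrum.frequencies, spectrum.re_k, label="Re[K]")
    ax.semilogx(spectrum.frequencies, spectrum.im_k, label="Im[K]", ls="--")
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("Clausius–Mossotti factor")
    ax.set_ylim(-0.6, 1.05)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_trajectory(fmap: FieldMap, result: TrajectoryResult, path: str | Path) -> Path:
    """Particle path over the unit cell's log |E|² background."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.pcolormesh(
        fmap.x * 1e6,
        fmap.y * 1e6,
        np.log10(np.maximum(fmap.e_sq, fmap.e_sq[fmap.e_sq > 0].min() if (fmap.e_sq > 0).any() else 1.0)),
        shading="auto",
    )
    p = result.positions
    ax.plot(p[:, 0] * 1e6, p[:, 1] * 1e6, ".-", color="w", ms=2, lw=0.7)
    ax.plot(p[0, 0] * 1e6, p[0, 1] * 1e6, "o", color="lime", ms=5)
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    ax.set_title(f"outcome: {result.outcome}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
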