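"""Simple diagnostic figures (expirograms, axial snapshots, flow sweeps)."""

from __future__ import annotations

import numpy as np


def _get_ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_expirogram(expirogram, ax=None, against="volume", **kwargs):
    """Mouth concentration against exhaled volume (default) or time."""
    ax = _get_ax(ax)
    x = expirogram.volume_ml if against == "volume" else expirogram.time_s
    ax.plot(x, expirogram.co_ppb, **kwargs)
    ax.set_xlabel("exhaled volume (ml)" if against == "volume" else "time (s)")
    ax.set_ylabel("CO (ppb)")
    return ax


def plot_snapshots(snapshots, ax=None):
    """Axial concentration distributions for several maneuver instants."""
    ax = _get_ax(ax)
    for snap in snapshots:
        ax.plot(snap.z_cm, snap.co_ppb, label=snap.label)
    ax.set_xlabel("axial position (cm)")
    ax.set_ylabel("CO (ppb)")
    ax.legend(fontsize="small")
    return ax


def plot_flow_sweep(sweep, ax=None):
    """End-tidal concentration versus exhalation flow rate."""
    ax = _get_ax(ax)
    ax.plot(sweep["efr_ml_s"], sweep["end_tidal_ppb"], "o-")
    ax.axhline(
        float(sweep["alveolar_equilibrium_ppb"].iloc[0]),
        ls="--", c="gray", label="alveolar equilibrium",
    )
    ax.set_xlabel("EFR (ml/s)")
    ax.set_ylabel("end-tidal CO (ppb)")
    ax.legend()
    return ax


def plot_fit(results, index: int = 0, ax=None):
    """Overlay measured samples and the fitted model curve."""
    ax = _get_ax(ax)
    data = results.model.data[index]
    sim = results.fitted_expirograms[index]
    ax.plot(data.volume_ml, data.co_ppb, ".", ms=3, alpha=0.6, label="measured")
    ax.plot(sim.volume_ml, sim.co_ppb, "-", label="fitted model")
    ax.set_xlabel("exhaled volume (ml)")
    ax.set_ylabel("CO (ppb)")
    ax.legend()
    return ax
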