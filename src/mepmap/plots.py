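"""Figure rendering: polar orientation profiles and scalp t-maps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["polar_profile_figure", "tmap_figure"]


def polar_profile_figure(profile, preference=None, path=None, title=""):
    """Normalised MEP amplitude vs coil orientation on polar axes.

    The radial axis is normalised amplitude in [0, 1]; an arrow marks the
    mean resultant vector when a preference is supplied.
    """
    ang = np.deg2rad(np.asarray(profile.angles_deg, dtype=float))
    amp = np.asarray(profile.amplitudes, dtype=float)
    order = np.argsort(ang)
    ang, amp = ang[order], amp[order]
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(4, 4))
    ax.plot(np.r_[ang, ang[0]], np.r_[amp, amp[0]], "o-", color="k")
    if preference is not None and preference.preferred_angle_deg is not None:
        ax.annotate(
            "",
            xy=(np.deg2rad(preference.preferred_angle_deg), preference.resultant_length),
            xytext=(0, 0),
            arrowprops={"color": "crimson", "arrowstyle": "-|>", "lw": 2},
        )
    ax.set_title(title)
    if path:
        fig.savefig(Path(path), dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def tmap_figure(tmap, path=None, cmap="viridis"):
    """Interpolated t map with stimulated sites and the threshold contour.

    Significant sites (t above the threshold) are drawn in red, others in
    black; the thick contour outlines the significant map region.
    """
    r = tmap.raster
    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.pcolormesh(r.x_mm, r.y_mm, np.ma.masked_invalid(r.values),
                       shading="nearest", cmap=cmap)
    fig.colorbar(im, ax=ax, label="t statistic")
    sig = set(tmap.significant_ids)
    for loc, x, y in tmap.layout.locations:
        ax.plot(x, y, "o", color="red" if loc in sig else "black", ms=5)
    for c in tmap.contours:
        ax.plot(c[:, 0], c[:, 1], "k-", lw=2)
    ax.plot(0, 0, "w+", ms=10, mew=2)  # Cz
    ax.set_xlabel("lateral (mm, + right)")
    ax.set_ylabel("anterior (mm, + nasion)")
    ax.set_aspect("equal")
    ax.set_title(f"area {tmap.area_mm2:.0f} mm$^2$ at t > {tmap.t_crit:.2f}")
    if path:
        fig.savefig(Path(path), dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
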