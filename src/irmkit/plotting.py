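"""Quick-look plots for fringe profiles and lens reconstructions."""

from __future__ import annotations

# channel false colors follow the usual IRM convention: cyan for the short
# wavelength, magenta for the long one
_CHANNEL_COLORS = ("c", "m", "y", "k")


def plot_radial_profile(profile, ax=None):
    """Intensity vs radius, one line per channel."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for color, lam in zip(_CHANNEL_COLORS, sorted(profile.intensities)):
        ax.plot(profile.radii, profile.intensities[lam], color, label=f"{lam:.0f} nm")
    ax.set_xlabel("radius (μm)")
    ax.set_ylabel("intensity (arb. u.)")
    ax.legend()
    return ax


def plot_line_profile(profile, ax=None):
    """Two-channel intensity along the cell body."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for color, lam in zip(_CHANNEL_COLORS, sorted(profile.intensities)):
        ax.plot(profile.arclength, profile.intensities[lam], color, label=f"{lam:.0f} nm")
    ax.set_xlabel("arclength (μm)")
    ax.set_ylabel("intensity (arb. u.)")
    ax.legend()
    return ax


def plot_lens_reconstruction(cloud, ax=None, subsample: int = 20):
    """3D scatter of a reconstructed lens point cloud (``reconstruct_lens``)."""
    import matplotlib.pyplot as plt

    if ax is None:
        fig = plt.figure()
        ax = fig.add_subplot(projection="3d")
    pts = cloud.iloc[::subsample]
    intensity_cols = [c for c in cloud.columns if c.startswith("I_")]
    color = pts[intensity_cols[0]] if intensity_cols else None
    ax.scatter(pts["x_um"], pts["y_um"], pts["z_nm"], c=color, s=1, cmap="viridis")
    ax.set_xlabel("x (μm)")
    ax.set_ylabel("y (μm)")
    ax.set_zlabel("z (nm)")
    return ax
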