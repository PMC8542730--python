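"""Radar plots of cluster phenotype profiles.

One polar figure per cluster: the cluster's scaled variable profile as a
polygon over the cohort-average reference ring (continuous variables are
cluster-median / cohort-median ratios; binary variables cluster vs cohort
proportions, both scaled to the cohort reference so the ring sits at 1).
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def radar_coordinates(profile: pd.DataFrame, cluster) -> pd.DataFrame:
    """The (variable, angle, radius, reference_radius) geometry for one
    cluster, with radii scaled so the cohort reference ring is at 1."""
    sub = profile[profile["cluster"] == cluster].reset_index(drop=True)
    if sub.empty:
        raise ValueError(f"cluster {cluster!r} not in profile")
    n = len(sub)
    angles = 2.0 * np.pi * np.arange(n) / n
    ref = sub["cohort_reference"].to_numpy(dtype=float)
    val = sub["value"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        radius = np.where(ref != 0, val / ref, np.nan)
    return pd.DataFrame(
        {"variable": sub["variable"], "angle": angles,
         "radius": radius, "reference_radius": 1.0}
    )


def render_radar(profile: pd.DataFrame, outdir=None, fmt: str = "svg"):
    """Render one radar figure per cluster; returns paths (or figures if
    ``outdir`` is None)."""
    if profile.empty:
        raise ValueError("empty profile table")
    outputs = []
    for cluster in pd.unique(profile["cluster"]):
        geom = radar_coordinates(profile, cluster)
        angles = np.concatenate([geom["angle"], geom["angle"][:1]])
        radii = np.concatenate([geom["radius"], geom["radius"][:1]])
        fig, ax = plt.subplots(subplot_kw={"projection": "polar"},
                               figsize=(4.5, 4.5))
        ax.plot(angles, np.ones_like(angles), color="tab:orange", lw=1.5,
                label="cohort average")
        ax.plot(angles, radii, color="tab:blue", lw=1.5, label=str(cluster))
        ax.fill(angles, np.nan_to_num(radii, nan=1.0), color="tab:blue",
                alpha=0.15)
        ax.set_xticks(geom["angle"])
        ax.set_xticklabels(geom["variable"], fontsize=7)
        ax.set_title(f"Cluster {cluster}", fontsize=10)
        ax.legend(loc="lower right", bbox_to_anchor=(1.15, -0.1), fontsize=7)
        if outdir is None:
            outputs.append(fig)
        else:
            path = Path(outdir) / f"radar_{cluster}.{fmt}"
            path.parent.mkdir(parents=True, exist_ok=True)
            fig.savefig(path, bbox_inches="tight")
            plt.close(fig)
            outputs.append(path)
    return outputs
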