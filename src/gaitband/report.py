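"""Deviation and spatiotemporal report bundles.

``render_report`` writes deterministic tabular outputs (per-station
Z-scores, flagged regions, spatiotemporal percent changes) and, when
requested, band plots in the conventional clinical style: the patient
curve drawn over the normative mean with a gray ±1 SD band and flagged
|Z| >= threshold regions shaded.
"""
from __future__ import annotations

import json
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .containers import NormalizedCycle
from .deviation import DeviationProfile, NormativeBand
from .io import write_deviation_csv, write_regions_json
from .spatiotemporal import SessionComparison


def plot_deviation_bands(profile: DeviationProfile, band: NormativeBand,
                         patient: NormalizedCycle, path,
                         patient_label: str = "patient") -> None:
    """One panel per joint: normative mean (dashed) ± 1 SD band (gray),
    patient curve (red), flagged regions shaded."""
    joints = sorted(band.joints)
    fig, axes = plt.subplots(1, len(joints), figsize=(4.2 * len(joints), 3.4),
                             squeeze=False)
    stations = patient.stations
    for ax, j in zip(axes[0], joints):
        mu, sd = band.mu[j], band.sigma[j]
        ax.fill_between(stations, mu - sd, mu + sd, color="0.8",
                        label="normative ±1 SD")
        ax.plot(stations, mu, "k--", lw=1.2, label="normative mean")
        ax.plot(stations, patient.angles[j], "r-", lw=1.5, label=patient_label)
        if profile.regions is not None:
            for r in profile.regions.get(j, []):
                ax.axvspan(r.start, r.end, color="gold", alpha=0.35)
        ax.set_title(j.replace("_", " "))
        ax.set_xlabel("gait cycle (%)")
        ax.set_ylabel("angle (deg)")
        ax.set_xlim(0, 100)
    axes[0][0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_session_bars(comparison: SessionComparison, path) -> None:
    """Pre/post bar chart with percent-change annotations."""
    params = ["speed", "stride_length", "step_width", "cadence",
              "double_support_s", "step_length_symmetry"]
    pre = comparison.pre.as_dict()
    post = comparison.post.as_dict()
    fig, axes = plt.subplots(1, len(params), figsize=(2.3 * len(params), 3.2))
    for ax, p in zip(axes, params):
        ax.bar([0, 1], [pre[p], post[p]], color=["tab:red", "tab:blue"],
               tick_label=["pre", "post"])
        change = comparison.percent_changes[p]
        if np.isfinite(change):
            ax.set_title(f"{p}\n{change:+.1f}%", fontsize=9)
        else:
            ax.set_title(p, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def render_report(out_dir,
                  deviations: dict | None = None,
                  band: NormativeBand | None = None,
                  patients: dict | None = None,
                  spatiotemporal: SessionComparison | None = None,
                  metadata: dict | None = None,
                  plots: bool = False) -> dict:
    """Write a report bundle and return the paths written.

    ``deviations`` maps a label (e.g. "pre", "post") to a flagged
    DeviationProfile; ``patients`` maps the same labels to the patient
    cycles (needed for plots).  Plot files are produced only when
    ``plots`` is set.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}

    summary = {"metadata": metadata or {}}
    if band is not None:
        summary["normative_band"] = {
            "n_subjects": band.n_subjects,
            "provenance": band.provenance,
            "note": "reference cohort provenance should be reported alongside "
                    "patient deviations",
        }
    if deviations:
        summary["deviation_regions"] = {}
        for label, profile in sorted(deviations.items()):
            dev_csv = out / f"deviations_{label}.csv"
            regions_json = out / f"regions_{label}.json"
            write_deviation_csv(dev_csv, profile)
            write_regions_json(regions_json, profile)
            written[f"deviations_{label}"] = dev_csv
            written[f"regions_{label}"] = regions_json
            summary["deviation_regions"][label] = sum(
                len(v) for v in (profile.regions or {}).values())
            if plots and band is not None and patients and label in patients:
                png = out / f"bands_{label}.png"
                plot_deviation_bands(profile, band, patients[label], png,
                                     patient_label=label)
                written[f"plot_{label}"] = png
    if spatiotemporal is not None:
        rows = ["parameter,pre,post,percent_change,direction"]
        pre, post = spatiotemporal.pre.as_dict(), spatiotemporal.post.as_dict()
        for p in sorted(pre):
            rows.append(f"{p},{pre[p]:.6g},{post[p]:.6g},"
                        f"{spatiotemporal.percent_changes[p]:.6g},"
                        f"{spatiotemporal.directions[p]}")
        spt_csv = out / "spatiotemporal_comparison.csv"
        spt_csv.write_text("\n".join(rows) + "\n")
        written["spatiotemporal"] = spt_csv
        if plots:
            png = out / "spatiotemporal_bars.png"
            plot_session_bars(spatiotemporal, png)
            written["plot_spatiotemporal"] = png

    summary_path = out / "summary.json"
    with open(summary_path, "w", newline="\n") as f:
        json.dump(summary, f, indent=2, sort_keys=True, default=str)
        f.write("\n")
    written["summary"] = summary_path
    return written
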