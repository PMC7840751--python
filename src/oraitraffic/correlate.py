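"""Panel synthesis: CC probability vs percent-PM across Orai variants.

Joins per-construct coiled-coil profiles with per-construct percent-PM
measurements and reports the Pearson correlation between maximal CC
probability and the egg-stage percent-PM (the isoform-series analysis). The
correlation routine is the same implementation used for PM-plane pixel
colocalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .coils import CoilsProfile
from .stats import StatsError, pearson_r


class CorrelateError(ValueError):
    """Raised for unjoinable or too-small panels."""


@dataclass(frozen=True)
class PanelRecord:
    """One construct's CC strength and PM-residence measurements."""

    name: str
    max_cc_probability: float
    best_window: int
    percent_pm_oocyte: float
    percent_pm_egg: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_cc_probability <= 1.0:
            raise CorrelateError(f"{self.name}: probability outside [0, 1]")
        for fieldname in ("percent_pm_oocyte", "percent_pm_egg"):
            v = getattr(self, fieldname)
            if not 0.0 <= v <= 100.0:
                raise CorrelateError(f"{self.name}: {fieldname} outside [0, 100]")

    @property
    def internalization(self) -> float:
        """Drop in percent-PM across maturation (oocyte − egg)."""
        return self.percent_pm_oocyte - self.percent_pm_egg


def build_panel(profiles: dict[str, tuple[int, CoilsProfile]],
                quant: dict[str, tuple[float, float]],
                y: str = "percent_pm_egg",
                ) -> tuple[list[PanelRecord], float]:
    """Join profiles with (oocyte, egg) percent-PM and correlate.

    ``profiles`` maps construct name -> (best_window, profile); ``quant``
    maps name -> (percent_pm_oocyte, percent_pm_egg). Names must match
    exactly; fewer than 3 joined records refuse to correlate. ``y`` selects
    the response: egg-stage percent-PM (default) or "internalization".
    """
    missing = sorted(set(profiles) ^ set(quant))
    if missing:
        raise CorrelateError(f"construct names do not match across inputs: {missing}")
    records = []
    for name in profiles:
        window, profile = profiles[name]
        oocyte, egg = quant[name]
        records.append(
            PanelRecord(
                name=name,
                max_cc_probability=profile.max_probability,
                best_window=window,
                percent_pm_oocyte=oocyte,
                percent_pm_egg=egg,
            )
        )
    if len(records) < 3:
        raise CorrelateError(
            f"need >= 3 joined records for a correlation, got {len(records)}"
        )
    if y not in ("percent_pm_egg", "internalization"):
        raise CorrelateError(f"unknown response {y!r}")
    xs = [r.max_cc_probability for r in records]
    ys = [getattr(r, y) for r in records]
    try:
        r = pearson_r(xs, ys)
    except StatsError as exc:
        raise CorrelateError(str(exc)) from exc
    return records, r


def panel_frame(records: list[PanelRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "name": r.name,
                "max_cc_probability": r.max_cc_probability,
                "best_window": r.best_window,
                "percent_pm_oocyte": r.percent_pm_oocyte,
                "percent_pm_egg": r.percent_pm_egg,
                "internalization": r.internalization,
            }
            for r in records
        ]
    )


def report(records: list[PanelRecord], r: float, output_dir: str | Path,
           profiles: dict[str, tuple[int, CoilsProfile]] | None = None,
           ) -> dict[str, Path]:
    """Write the panel CSV, a scatter of percent-PM vs CC probability, and
    optional per-construct probability profiles. Deterministic given inputs.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not records:
        raise CorrelateError("empty panel")
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    csv_path = out / "panel.csv"
    panel_frame(records).to_csv(csv_path, index=False, float_format="%.6f")
    paths["panel_csv"] = csv_path

    fig, ax = plt.subplots(figsize=(4.5, 4))
    xs = [rec.max_cc_probability for rec in records]
    ys = [rec.percent_pm_egg for rec in records]
    ax.scatter(xs, ys, color="tab:blue", zorder=3)
    for rec in records:
        ax.annotate(
            f"{rec.name} ({rec.best_window})",
            (rec.max_cc_probability, rec.percent_pm_egg),
            textcoords="offset points", xytext=(5, 5), fontsize=8,
        )
    ax.set_xlabel("maximal CC probability")
    ax.set_ylabel("percent at PM (egg)")
    ax.set_title(f"Pearson r = {r:.3f}")
    fig.tight_layout()
    scatter_path = out / "cc_vs_percent_pm.png"
    fig.savefig(scatter_path, dpi=150)
    plt.close(fig)
    paths["scatter"] = scatter_path

    if profiles:
        fig, ax = plt.subplots(figsize=(6, 4))
        for name, (window, profile) in profiles.items():
            ax.plot(profile.offsets, profile.probabilities,
                    label=f"{name} ({window})")
        ax.set_xlabel("residue (full-length numbering)")
        ax.set_ylabel("CC probability")
        ax.set_ylim(-0.02, 1.02)
        ax.legend(fontsize=8)
        fig.tight_layout()
        prof_path = out / "cc_profiles.png"
        fig.savefig(prof_path, dpi=150)
        plt.close(fig)
        paths["profiles"] = prof_path

    return paths
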