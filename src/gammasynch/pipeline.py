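"""Orchestration of a full virtual experiment.

Generates every condition group from its preset, runs all analyses
(ASSR evoked/total/baseline power, intertrial coherence, N1; spike-pair
cross-correlation with shuffle null; synchronous sIPSC percentage and
inter-event intervals; Y-maze alternation and %PPI), aggregates under
both the per-animal and per-channel designs, and writes a metric table,
a JSON summary of condition contrasts with sign/ordering checks, and
optional figure panels.  Fully reproducible from (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import assr, ipsc, spikes
from .datatypes import metric_table
from .presets import make_preset, registered_labels
from .quant import alternation_index, ppi_percent
from .synthetic import (
    generate_assr_trials,
    generate_event_train_pair,
    generate_ppi_session,
    generate_spike_pair,
    generate_ymaze_session,
)

DEFAULT_LABELS = ("control", "mutant", "mutant_gsk3b_inhibited",
                  "mutant_gsk3b_knockdown")

# Expected direction of the mutant-vs-control contrast for each metric
# (negative = reduced in the mutant).  All but N1 are expected to be
# restored to control level by the GSK3β-manipulated presets.
CONTRAST_DIRECTIONS = {
    "evoked": -1, "total": -1, "baseline": +1, "itc": -1, "n1": -1,
    "spike_r": -1, "ipsc_pct_sync": -1, "alternation": -1, "ppi": -1,
}
NOT_RESTORED = ("n1",)


@dataclass
class RunConfig:
    """Configuration of one virtual experiment."""

    labels: tuple[str, ...] = DEFAULT_LABELS
    n_animals: int = 5
    channels_per_animal: int = 3   # 15 channels / 5 mice per group
    n_trials: int = 50
    seed: int = 0
    band: tuple[float, float] = (35.0, 44.0)
    spike_pairs: int = 15
    spike_duration: float = 120.0
    spike_bin_width: float = 0.005
    n_shuffles: int = 50
    ipsc_pairs: dict = field(default_factory=lambda: {
        "control": 11, "mutant": 10,
        "mutant_gsk3b_inhibited": 8, "mutant_gsk3b_knockdown": 11,
    })
    ipsc_duration: float = 300.0
    behavior_subjects: int = 10
    ymaze_entries: int = 20
    make_plots: bool = False

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        for name in ("n_animals", "channels_per_animal", "n_trials",
                     "spike_pairs", "behavior_subjects"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        unknown = set(self.labels) - set(registered_labels())
        if unknown:
            raise ValueError(f"unknown condition labels: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        from .io import load_yaml

        raw = load_yaml(path)
        if "band" in raw:
            raw["band"] = tuple(raw["band"])
        if "labels" in raw:
            raw["labels"] = tuple(raw["labels"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["labels"] = list(self.labels)
        d["band"] = list(self.band)
        return d


class _SeedStream:
    """Deterministic stream of child seeds derived from the root seed."""

    def __init__(self, root: int):
        self._ss = np.random.SeedSequence(root)

    def next(self) -> np.random.SeedSequence:
        return self._ss.spawn(1)[0]


def _assr_rows(config: RunConfig, label, preset, seeds) -> list[dict]:
    rows = []
    for a in range(config.n_animals):
        subject = f"{label}_m{a}"
        for c in range(config.channels_per_animal):
            ts = generate_assr_trials(
                preset, n_trials=config.n_trials, seed=seeds.next(),
                subject_id=subject, channel_id=f"ch{c}",
            )
            z = assr.zscore_lfp(ts)
            values = {
                "evoked": assr.assr_power(z, "evoked", band=config.band).value,
                "total": assr.assr_power(z, "total", band=config.band).value,
                "baseline": assr.baseline_power(z, band=config.band).value,
                "itc": assr.intertrial_coherence(z, band=config.band).band_value,
                "n1": assr.n1_amplitude(z).amplitude,
            }
            rows += [
                dict(condition=label, subject=subject, channel=f"ch{c}",
                     metric=m, value=v)
                for m, v in values.items()
            ]
    return rows


def _spike_rows(config: RunConfig, label, preset, seeds) -> list[dict]:
    rows = []
    for p in range(config.spike_pairs):
        pair = generate_spike_pair(
            preset.spike_rate, preset.spike_shared_frac,
            config.spike_duration, seed=seeds.next(),
        )
        null = spikes.shuffle_null(
            pair, n_shuffles=config.n_shuffles, seed=seeds.next(),
            bin_width=config.spike_bin_width,
        )
        subject = f"{label}_pair{p}"
        rows.append(dict(condition=label, subject=subject, channel="t0",
                         metric="spike_r", value=null.observed))
        rows.append(dict(condition=label, subject=subject, channel="t0",
                         metric="spike_null_quantile", value=null.quantile))
    return rows


def _ipsc_rows(config: RunConfig, label, preset, seeds) -> list[dict]:
    rows = []
    n_pairs = config.ipsc_pairs.get(label, 10)
    for p in range(n_pairs):
        trains = generate_event_train_pair(
            preset.ipsc_indep_rate, preset.ipsc_shared_rate,
            config.ipsc_duration, seed=seeds.next(),
        )
        res = ipsc.synchronous_fraction(trains)
        subject = f"{label}_pair{p}"
        rows.append(dict(condition=label, subject=subject, channel="cellpair",
                         metric="ipsc_pct_sync", value=res.pct_synchronous))
        rows.append(dict(
            condition=label, subject=subject, channel="cellpair",
            metric="ipsc_mean_iei_ms",
            value=1e3 * np.nanmean([res.mean_iei_a, res.mean_iei_b]),
        ))
    return rows


def _behavior_rows(config: RunConfig, label, preset, seeds) -> list[dict]:
    rows = []
    for s in range(config.behavior_subjects):
        subject = f"{label}_b{s}"
        session = generate_ymaze_session(
            "lapse", n_entries=config.ymaze_entries,
            lapse=preset.alternation_lapse, seed=seeds.next(),
        )
        rows.append(dict(condition=label, subject=subject, channel="behavior",
                         metric="alternation",
                         value=alternation_index(session.entries)))
        startle = generate_ppi_session(preset, seed=seeds.next())
        ppi = ppi_percent(startle.table)
        for ttype, pct in ppi.items():
            rows.append(dict(condition=label, subject=subject,
                             channel="behavior", metric=f"ppi_{ttype}",
                             value=pct))
        rows.append(dict(condition=label, subject=subject, channel="behavior",
                         metric="ppi", value=float(np.mean(list(ppi.values())))))
    return rows


def evaluate_contrasts(per_animal: pd.DataFrame, labels=DEFAULT_LABELS) -> dict:
    """Sign/ordering checks of the condition contrasts on group means.

    For every metric in :data:`CONTRAST_DIRECTIONS`: the mutant-vs-
    control difference must have the expected sign; GSK3β-manipulated
    groups must be *restored* — recovery fraction
    ``(treated - mutant) / (control - mutant)`` above 0.5, with
    overshoot beyond control counting as restored — for every metric
    except N1, which must remain at the mutant level (recovery < 0.5).
    """
    means = (
        per_animal.groupby(["condition", "metric"], observed=True)["value"]
        .mean().unstack("metric")
    )
    treated = [lab for lab in labels if lab.startswith("mutant_gsk3b")]
    report: dict = {"metrics": {}, "all_ok": True}
    for metric, direction in CONTRAST_DIRECTIONS.items():
        if metric not in means.columns:
            continue
        ctrl = float(means.loc["control", metric])
        mut = float(means.loc["mutant", metric])
        deficit = mut - ctrl
        sign_ok = bool(np.sign(deficit) == direction)
        entry = {
            "group_means": {lab: float(means.loc[lab, metric]) for lab in labels},
            "expected_direction": "down" if direction < 0 else "up",
            "mutant_vs_control_ok": sign_ok,
            "restored": {},
        }
        ok = sign_ok
        for lab in treated:
            val = float(means.loc[lab, metric])
            # recovery 0 = stays at mutant level, 1 = back at control level
            recovery = (val - mut) / (ctrl - mut) if deficit != 0 else 0.0
            restored = recovery > 0.5
            if metric in NOT_RESTORED:
                entry["restored"][lab] = {
                    "expected": False, "recovery_fraction": recovery,
                    "stays_at_mutant_level": bool(not restored),
                }
                ok = ok and not restored
            else:
                entry["restored"][lab] = {
                    "expected": True, "recovery_fraction": recovery,
                    "observed": bool(restored),
                }
                ok = ok and restored
        entry["ok"] = bool(ok)
        report["metrics"][metric] = entry
        report["all_ok"] = report["all_ok"] and ok
    return report


@dataclass
class ExperimentReport:
    per_channel: pd.DataFrame
    per_animal: pd.DataFrame
    contrasts: dict
    out_dir: Path | None


def run_experiment(config: RunConfig, out_dir=None) -> ExperimentReport:
    """Run the full virtual experiment described by ``config``.

    Returns the tidy metric tables under both designs and the contrast
    report; if ``out_dir`` is given, writes ``metrics_per_channel.csv``,
    ``metrics_per_animal.csv``, ``contrasts.json``, ``config.yaml`` and
    (optionally) ``figure_panels.png`` there.
    """
    seeds = _SeedStream(config.seed)
    rows: list[dict] = []
    for label in config.labels:
        preset = make_preset(label)
        try:
            rows += _assr_rows(config, label, preset, seeds)
            rows += _spike_rows(config, label, preset, seeds)
            rows += _ipsc_rows(config, label, preset, seeds)
            rows += _behavior_rows(config, label, preset, seeds)
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"stage failed for condition {label!r}: {exc}") from exc

    per_channel = metric_table(rows)
    per_animal = assr.aggregate(per_channel, "per_animal")
    contrasts = evaluate_contrasts(per_animal, config.labels)

    out_path = None
    if out_dir is not None:
        out_path = Path(out_dir)
        out_path.mkdir(parents=True, exist_ok=True)
        per_channel.to_csv(out_path / "metrics_per_channel.csv", index=False)
        per_animal.to_csv(out_path / "metrics_per_animal.csv", index=False)
        with open(out_path / "contrasts.json", "w") as f:
            json.dump(contrasts, f, indent=2, sort_keys=True)
        from .io import dump_yaml

        dump_yaml(config.to_dict(), out_path / "config.yaml")
        if config.make_plots:
            plot_panels(per_animal, out_path / "figure_panels.png")
    return ExperimentReport(per_channel=per_channel, per_animal=per_animal,
                            contrasts=contrasts, out_dir=out_path)


def plot_panels(per_animal: pd.DataFrame, path) -> None:
    """Bar panels of group means per metric, mirroring the study's layout."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    metrics = [m for m in CONTRAST_DIRECTIONS if
               m in set(per_animal["metric"])]
    fig, axes = plt.subplots(3, 3, figsize=(12, 10))
    for ax, metric in zip(axes.ravel(), metrics):
        sub = per_animal[per_animal["metric"] == metric]
        means = sub.groupby("condition", observed=True, sort=False)["value"].mean()
        sems = sub.groupby("condition", observed=True, sort=False)["value"].sem()
        ax.bar(range(len(means)), means.values, yerr=sems.values, capsize=3)
        ax.set_xticks(range(len(means)))
        ax.set_xticklabels(means.index, rotation=45, ha="right", fontsize=7)
        ax.set_title(metric)
    for ax in axes.ravel()[len(metrics):]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
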