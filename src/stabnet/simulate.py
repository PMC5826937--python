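"""Synthetic plasma-metabolome storage experiment generator.

Emulates the statistical design of a pooled-plasma storage-stability study:
aliquots of one pooled plasma sample are held at -20 degC and ten aliquots
are moved to -80 degC every ``day_step`` days, giving ``n_timepoints``
storage days x ``n_replicates`` replicate aliquots. Technical quality is
monitored with repeated injections of a pooled QC sample and a QC dilution
series at known relative concentrations.

The per-feature intensity model is log-linear:

    log2 I = baseline + slope * day + replicate_offset + noise

with multiplicative lognormal noise parameterized by a fractional CV.
Feature classes:

* ``increasing`` / ``decreasing`` -- monotone trend, slope drawn from
  ``slope_range`` (sign per class); these are the "trending" ground truth a
  feature-selection method should recover.
* ``erratic`` -- i.i.d. day-level mean shifts with no linear trend.
* ``stable`` -- flat in time.
* ``background`` -- flat in time and *not* responding to the QC dilution
  series (instrument/background signal).
* ``noisy_qc`` -- flat in time but with QC injection CV above the usual
  30% acceptance threshold.

Non-detected study cells are written as exact zeros (the convention of
vendor peak-table exports); the zero-to-missing conversion is the first
pipeline stage.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import FeatureTable

LN2 = np.log(2.0)


class SyntheticConfigError(ValueError):
    """Invalid synthetic experiment configuration."""


def _cv_to_log2_sd(cv: float) -> float:
    """SD on the log2 scale of lognormal noise with fractional CV `cv`."""
    if cv <= 0:
        return 0.0
    return float(np.sqrt(np.log1p(cv * cv)) / LN2)


@dataclass
class SyntheticConfig:
    """Parameters of the simulated storage experiment.

    Defaults mirror the emulated study design: 11 time points (day 0..30,
    step 3) x 10 replicate aliquots, QC replicate injections, and a QC
    dilution series at relative concentrations {1, 1/5, 1/10, 1/50}.
    """

    n_features: int = 1500
    n_timepoints: int = 11
    day_step: int = 3
    n_replicates: int = 10
    n_increasing: int = 30
    n_decreasing: int = 30
    n_erratic: int = 30
    slope_range: tuple[float, float] = (0.03, 0.10)  # log2 units per day
    replicate_noise_cv: float = 0.20
    replicate_offset_sd: float = 0.05  # persistent per-aliquot log2 offset
    erratic_shift_sd: float = 0.5  # log2 SD of i.i.d. day-level shifts
    qc_n_injections: int = 5
    qc_noise_cv: float = 0.10
    noisy_qc_cv: float = 0.60
    qc_dilution_factors: tuple[float, ...] = (1.0, 0.2, 0.1, 0.02)
    qc_dilution_replicates: int = 2  # injections per dilution level
    frac_background_features: float = 0.30
    frac_noisy_qc_features: float = 0.10
    missing_rate: float = 0.05
    missing_low_bias: bool = False
    baseline_log2_mean: float = 17.0
    baseline_log2_sd: float = 1.5
    mode: str = "pos"
    seed: int = 0

    def validate(self) -> None:
        n_classed = self.n_increasing + self.n_decreasing + self.n_erratic
        if n_classed > self.n_features:
            raise SyntheticConfigError(
                f"class counts ({n_classed}) exceed n_features ({self.n_features})"
            )
        for name in ("frac_background_features", "frac_noisy_qc_features",
                     "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SyntheticConfigError(f"{name}={v} outside [0, 1]")
        lo, hi = self.slope_range
        if lo > hi:
            raise SyntheticConfigError("slope_range low > high")
        if self.n_timepoints < 2 or self.n_replicates < 1:
            raise SyntheticConfigError("need >=2 timepoints and >=1 replicate")

    @property
    def days(self) -> np.ndarray:
        return np.arange(self.n_timepoints) * self.day_step


@dataclass
class SyntheticTruth:
    """Per-feature generative ground truth for recovery scoring."""

    table: pd.DataFrame  # index feature_id: class, slope, baseline
    config: SyntheticConfig

    @property
    def trending_ids(self) -> set[str]:
        m = self.table["class"].isin(["increasing", "decreasing"])
        return set(self.table.index[m])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="feature_id")


def generate_experiment(config: SyntheticConfig) -> tuple[FeatureTable, SyntheticTruth]:
    """Simulate one full experiment; same seed gives byte-identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    p = config.n_features
    days = config.days
    k, n_rep = config.n_timepoints, config.n_replicates

    # --- feature classes --------------------------------------------------
    classes = np.array(["stable"] * p, dtype=object)
    i = 0
    for cls, cnt in (("increasing", config.n_increasing),
                     ("decreasing", config.n_decreasing),
                     ("erratic", config.n_erratic)):
        classes[i:i + cnt] = cls
        i += cnt
    n_bg = int(round(config.frac_background_features * p))
    n_noisy = int(round(config.frac_noisy_qc_features * p))
    n_bg = min(n_bg, p - i)
    classes[i:i + n_bg] = "background"
    n_noisy = min(n_noisy, p - i - n_bg)
    classes[i + n_bg:i + n_bg + n_noisy] = "noisy_qc"
    # shuffle so class is independent of feature order / rt
    order = rng.permutation(p)
    classes = classes[order]

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, p)
    slopes = np.zeros(p)
    lo, hi = config.slope_range
    inc = classes == "increasing"
    dec = classes == "decreasing"
    slopes[inc] = rng.uniform(lo, hi, inc.sum())
    slopes[dec] = -rng.uniform(lo, hi, dec.sum())

    # feature metadata: rt in 0-8.5 min window, mz 50-1000 Da
    rt = np.sort(rng.uniform(0.2, 8.5, p))
    mz = rng.uniform(50.0, 1000.0, p)
    feature_ids = [f"{r:.2f}_{m:.4f}" for r, m in zip(rt, mz)]
    if len(set(feature_ids)) != p:  # astronomically unlikely; keep ids unique
        feature_ids = [f"{fid}_{j}" for j, fid in enumerate(feature_ids)]

    # --- study samples ----------------------------------------------------
    noise_sd = _cv_to_log2_sd(config.replicate_noise_cv)
    rep_offsets = rng.normal(0.0, config.replicate_offset_sd, (n_rep, p))
    day_shift = np.zeros((k, p))
    err = classes == "erratic"
    day_shift[:, err] = rng.normal(0.0, config.erratic_shift_sd, (k, err.sum()))

    sample_rows = []
    log2_rows = []
    for d_idx, day in enumerate(days):
        for r in range(n_rep):
            mean = baseline + slopes * day + day_shift[d_idx] + rep_offsets[r]
            log2_rows.append(mean + rng.normal(0.0, noise_sd, p))
            sample_rows.append(
                (f"S_d{day:02d}_r{r:02d}", "study", day, f"r{r:02d}",
                 np.nan, config.mode)
            )
    study = 2.0 ** np.asarray(log2_rows)

    # missingness among study samples (written as zeros: non-detects)
    if config.missing_rate > 0:
        if config.missing_low_bias:
            # probability inversely tied to log2 intensity rank
            ranks = np.argsort(np.argsort(study, axis=None)).reshape(study.shape)
            prob = config.missing_rate * 2.0 * (1.0 - ranks / ranks.size)
            mask = rng.random(study.shape) < prob
        else:
            mask = rng.random(study.shape) < config.missing_rate
        study[mask] = 0.0

    # --- QC replicate injections -----------------------------------------
    # pooled QC approximates the across-sample mean composition
    qc_mean = baseline + slopes * days.mean()
    qc_sd = np.where(classes == "noisy_qc",
                     _cv_to_log2_sd(config.noisy_qc_cv),
                     _cv_to_log2_sd(config.qc_noise_cv))
    qc = 2.0 ** (qc_mean + rng.normal(0.0, 1.0, (config.qc_n_injections, p)) * qc_sd)
    for j in range(config.qc_n_injections):
        sample_rows.append((f"QC_{j:02d}", "qc", np.nan, np.nan, np.nan, config.mode))

    # --- QC dilution series ----------------------------------------------
    bg = classes == "background"
    dil_rows = []
    for j, fac in enumerate(config.qc_dilution_factors):
        mean = qc_mean + np.where(bg, 0.0, np.log2(fac))
        for rep in range(config.qc_dilution_replicates):
            dil_rows.append(2.0 ** (mean + rng.normal(0.0, 1.0, p) * qc_sd))
            sample_rows.append(
                (f"QCdil_{j:02d}_{rep:02d}", "qc_dilution", np.nan, np.nan,
                 fac, config.mode)
            )
    intens = np.vstack([study, qc, np.asarray(dil_rows)])

    sample_df = pd.DataFrame(
        sample_rows,
        columns=["sample_id", "role", "storage_day", "replicate",
                 "dilution_factor", "mode"],
    ).set_index("sample_id")
    feature_df = pd.DataFrame(
        {"rt_min": rt, "mz": mz, "mode": config.mode}, index=pd.Index(feature_ids)
    )
    table = FeatureTable(
        intensities=pd.DataFrame(intens, index=sample_df.index, columns=feature_ids),
        samples=sample_df,
        features=feature_df,
    )
    truth = SyntheticTruth(
        table=pd.DataFrame(
            {"class": classes, "slope": slopes, "baseline": baseline},
            index=pd.Index(feature_ids),
        ),
        config=config,
    )
    return table, truth


def score_recovery(
    selected_features: set[str] | list[str], truth: SyntheticTruth
) -> tuple[float | None, float]:
    """Precision/recall of a selected feature set against the trending truth.

    The target set is the union of the increasing and decreasing classes.
    An empty selection has undefined precision (returned as None) and
    recall 0.
    """
    selected = set(selected_features)
    unknown = selected - set(truth.table.index)
    if unknown:
        raise ValueError(f"selected ids not in truth: {sorted(unknown)[:5]}")
    trending = truth.trending_ids
    hits = len(selected & trending)
    precision = hits / len(selected) if selected else None
    recall = hits / len(trending) if trending else 0.0
    return precision, recall


def config_to_dict(config: SyntheticConfig) -> dict:
    d = asdict(config)
    d["slope_range"] = list(d["slope_range"])
    d["qc_dilution_factors"] = list(d["qc_dilution_factors"])
    return d
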