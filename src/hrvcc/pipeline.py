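"""Pipeline orchestration: per-subject measure extraction and cohort analysis.

``run_subject`` composes preprocessing, HRV metrics and complexity measures
into one flat row per recording; failures are recorded per subject so a
batch never aborts.  ``run_cohort`` applies the HR adjustment, the grouped
comparisons and the hierarchical regressions to a cohort table and writes
tidy CSVs for both unadjusted and adjusted measures.  Every output file
carries the configuration hash and seed in a header comment so identical
reruns are identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import cohort_stats
from .cohort_stats import MEASURE_FAMILIES, bonferroni_alpha
from .complexity import (
    AllometricConfig,
    DFAConfig,
    MSEConfig,
    allometric_exponent,
    dfa,
    multiscale_entropy,
)
from .hrv_metrics import SpectralConfig, spectral_measures, time_domain
from .io_filtering import FilterConfig, RawIBIRecording, preprocess, read_ibi_file
from .synthetic import SYMPTOM_COLUMNS, CohortSpec, SeriesSpec, gen_cohort, gen_series

__all__ = ["PipelineConfig", "run_subject", "run_cohort", "measures_from_recording"]


@dataclass(frozen=True)
class PipelineConfig:
    """All stage settings plus seed and base alpha, loadable from YAML."""

    filter: FilterConfig = field(default_factory=FilterConfig)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    dfa: DFAConfig = field(default_factory=DFAConfig)
    allometric: AllometricConfig = field(default_factory=AllometricConfig)
    mse: MSEConfig = field(default_factory=MSEConfig)
    base_alpha: float = 0.05
    hr_adjust: bool = True
    seed: Optional[int] = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: Dict[str, Any] = {}
        sections = {
            "filter": FilterConfig,
            "spectral": SpectralConfig,
            "dfa": DFAConfig,
            "allometric": AllometricConfig,
            "mse": MSEConfig,
        }
        for name, klass in sections.items():
            if name in raw:
                section = dict(raw[name])
                for key in ("aggregation_levels", "scale_factors", "short_range", "long_range", "lf_band", "hf_band"):
                    if key in section and isinstance(section[key], list):
                        section[key] = tuple(section[key])
                kwargs[name] = klass(**section)
        for key in ("base_alpha", "hr_adjust", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def to_dict(self) -> Dict[str, Any]:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def measures_from_recording(
    rec: RawIBIRecording, cfg: PipelineConfig | None = None
) -> Dict[str, float]:
    """All per-subject measures (plus filter accounting) as one flat dict."""
    cfg = cfg or PipelineConfig()
    clean = preprocess(rec, cfg.filter)
    x = clean.intervals

    td = time_domain(clean)
    spec = spectral_measures(clean, cfg.spectral)
    d = dfa(x, cfg.dfa)
    allo = allometric_exponent(x, cfg.allometric)
    mse = multiscale_entropy(x, cfg.mse)

    row: Dict[str, float] = {
        "avnn_ms": td.avnn,
        "hr_bpm": td.hr,
        "rmssd_ms": td.rmssd,
        "lf_ms2": spec.lf_power,
        "hf_ms2": spec.hf_power,
        "ln_hf": spec.ln_hf,
        "dfa_alpha1": d.alpha1,
        "dfa_alpha2": d.alpha2,
        "allometric_h": allo.h,
        "fd": allo.fd,
        "n_input": clean.report.n_input,
        "n_excluded_band": clean.report.n_excluded_band,
        "n_excluded_window": clean.report.n_excluded_window,
        "n_output": clean.report.n_output,
        "excluded_fraction": clean.report.excluded_fraction,
    }
    for scale, value in mse.sampen_by_scale.items():
        row[f"mse_s{scale}"] = value
    return row


def run_subject(
    source: str | Path | RawIBIRecording,
    cfg: PipelineConfig | None = None,
    dialect: str = "single_column",
) -> Dict[str, Any]:
    """One CSV-ready row for one recording; errors recorded, not raised."""
    cfg = cfg or PipelineConfig()
    if isinstance(source, RawIBIRecording):
        rec = source
    else:
        try:
            rec = read_ibi_file(source, dialect=dialect)
        except Exception as exc:  # parse failures are per-subject data errors
            return {"subject_id": Path(source).stem, "error": str(exc)}
    try:
        row = measures_from_recording(rec, cfg)
    except Exception as exc:
        return {"subject_id": rec.subject_id, "error": str(exc)}
    return {"subject_id": rec.subject_id, "error": "", **row}


def _write_csv(df: pd.DataFrame, path: Path, cfg: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg.config_hash} seed={cfg.seed}\n")
        df.to_csv(fh, index=False)


def run_cohort(
    cohort: pd.DataFrame | CohortSpec,
    cfg: PipelineConfig | None = None,
    outdir: str | Path | None = None,
    outcomes: Sequence[str] | None = None,
) -> Dict[str, pd.DataFrame]:
    """Cohort analysis: comparisons, regressions and the adjustment report.

    Returns (and, when ``outdir`` is given, writes) tidy frames:
    ``comparisons`` (one row per measure x adjustment state, Bonferroni
    alpha per family), ``regressions`` (per outcome x measure x adjustment
    state) and ``adjustment`` (correlation sign and operation per measure).
    """
    cfg = cfg or PipelineConfig()
    if isinstance(cohort, CohortSpec):
        cohort = gen_cohort(cohort)
    outcomes = list(outcomes) if outcomes is not None else [
        c for c in SYMPTOM_COLUMNS if c in cohort
    ]

    adjusted, report = cohort_stats.hr_adjust(cohort)
    adj_df = pd.DataFrame(
        {
            "measure": list(report.correlations),
            "correlation_with_hr": [report.correlations[m] for m in report.correlations],
            "operation": [report.operations[m] for m in report.correlations],
        }
    )

    comparison_frames = []
    for family, members in MEASURE_FAMILIES.items():
        members = [m for m in members if m in cohort.columns]
        if not members:
            continue
        alpha = bonferroni_alpha(cfg.base_alpha, len(members))
        for state, suffix in (("unadjusted", ""), ("adjusted", "_adj")):
            if state == "adjusted" and not cfg.hr_adjust:
                continue
            cols = [m + suffix for m in members if m + suffix in adjusted.columns]
            if not cols:
                continue
            frame = cohort_stats.compare_groups(adjusted, cols, family_alpha=alpha)
            frame.insert(0, "family", family)
            frame.insert(1, "adjustment", state)
            comparison_frames.append(frame)
    comparisons = pd.concat(comparison_frames, ignore_index=True)

    measure_cols = [m for fam in MEASURE_FAMILIES.values() for m in fam if m in cohort.columns]
    regression_frames = []
    for state, suffix in (("unadjusted", ""), ("adjusted", "_adj")):
        if state == "adjusted" and not cfg.hr_adjust:
            continue
        cols = [m + suffix for m in measure_cols if m + suffix in adjusted.columns]
        if not cols or not outcomes:
            continue
        frame = cohort_stats.regression_table(adjusted, outcomes, cols)
        frame.insert(0, "adjustment", state)
        regression_frames.append(frame)
    regressions = (
        pd.concat(regression_frames, ignore_index=True)
        if regression_frames
        else pd.DataFrame()
    )

    out = {"comparisons": comparisons, "regressions": regressions, "adjustment": adj_df}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in out.items():
            _write_csv(df, outdir / f"{name}.csv", cfg)
    return out
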