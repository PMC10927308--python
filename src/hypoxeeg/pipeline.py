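"""End-to-end study pipeline.

Runs synthesis (or EDF ingestion) -> preprocessing -> spectral analysis ->
wPLI connectivity -> graph topology -> paired statistics, and emits the
study-level tables: a long-format StudyTable of per-subject metrics,
condition-contrast results (raw and age-residualized), age correlations
for the four headline metrics, and a machine-readable run manifest.

Analysis families (FDR correction is applied within each):

* ``relative_power_global`` / ``relative_power_region`` — band power as a
  fraction of broadband (0.5-30 Hz) power.
* ``exponent_global`` / ``exponent_region`` — aperiodic 1/f exponent.
* ``overall_fc`` / ``nodal_strength_region`` — mean off-diagonal wPLI and
  weighted degree of the nonthresholded matrices.
* ``graph_global`` / ``nodal_efficiency_region`` /
  ``nodal_clustering_region`` — threshold-sweep AUCs of the binarized
  graph metrics.

Region-level values are the mean of channel-level values across the
region's channels, computed per subject before testing.  Overall FC is
computed on the weighted nonthresholded matrices; graph metrics on
thresholded binarized ones.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .channels import REGIONS
from .connectivity import band_wpli, nodal_strength
from .graph import DEFAULT_THRESHOLDS, metric_auc, threshold_sweep
from .preprocess import (
    BANDS,
    Recording,
    average_reference,
    bandpass,
    epoch,
    resample,
)
from .spectral import fit_aperiodic_all, relative_band_power, welch_psd
from .stats import bh_fdr, contrast_table, pearson_age_correlation, regress_out_age
from .synth import GroundTruth, SynthConfig, generate_study

#: The four headline metrics followed through the age analyses.
HEADLINE_METRICS = (
    ("relative_power", "alpha", "global"),
    ("exponent", "broadband", "global"),
    ("overall_fc", "delta", "global"),
    ("auc_global_efficiency", "theta", "global"),
)


@dataclass
class PipelineConfig:
    """Validated settings for one full study run."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    input_mode: str = "synthetic"  # "synthetic" | "edf_dir"
    edf_dir: str | None = None
    bands: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(BANDS))
    epoch_length_s: float = 12.0
    resample_hz: float | None = None
    broadband_filter: tuple[float, float] = (0.5, 45.0)
    fit_range: tuple[float, float] = (4.0, 40.0)
    n_tapers: int = 7
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    n_perm: int = 10_000
    seed: int = 0
    wpli_per_epoch: bool = False
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.input_mode not in ("synthetic", "edf_dir"):
            raise ValueError(f"unknown input_mode {self.input_mode!r}")
        if self.input_mode == "edf_dir" and not self.edf_dir:
            raise ValueError("edf_dir input_mode requires edf_dir")
        if self.epoch_length_s <= 0:
            raise ValueError("epoch_length_s must be positive")
        fs = self.resample_hz or self.synth.fs
        for name, (lo, hi) in self.bands.items():
            if not 0 <= lo < hi < fs / 2:
                raise ValueError(f"band {name}={lo, hi} incompatible with fs={fs}")
        if len(self.thresholds) < 2:
            raise ValueError("need at least 2 thresholds for AUC")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth_raw = raw.pop("synth", {})
        eff = synth_raw.pop("condition_effects", None)
        from .synth import ConditionEffects

        synth = SynthConfig(
            **synth_raw,
            **({"condition_effects": ConditionEffects(**eff)} if eff else {}),
        )
        if "bands" in raw:
            raw["bands"] = {k: tuple(v) for k, v in raw["bands"].items()}
        for key in ("broadband_filter", "fit_range", "thresholds"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(synth=synth, **raw)


@dataclass
class StudyResults:
    """Bundle returned by :func:`run_study`."""

    study_table: pd.DataFrame
    contrasts: pd.DataFrame
    contrasts_age_adjusted: pd.DataFrame
    age_correlations: pd.DataFrame
    manifest: dict
    ground_truth: GroundTruth | None = None


def preprocess_recording(rec: Recording, config: PipelineConfig) -> Recording:
    """Broadband filter -> (optional) resample -> average reference."""
    lo, hi = config.broadband_filter
    hi = min(hi, rec.fs / 2 - 1.0)
    rec = bandpass(rec, lo, hi, design="fir_broadband")
    if config.resample_hz and config.resample_hz < rec.fs:
        rec = resample(rec, config.resample_hz)
    return average_reference(rec)


def analyze_recording(rec: Recording, config: PipelineConfig) -> list[dict]:
    """All per-recording metrics as StudyTable rows (one subject-condition)."""
    rows: list[dict] = []
    base = {"subject_id": rec.subject_id, "condition": rec.condition}
    regions_of = [rec.region_map[c] for c in rec.channel_labels]

    def add(metric: str, band: str, channel_values: np.ndarray, family_prefix: str,
            global_too: bool = True):
        if global_too:
            rows.append(
                base
                | {
                    "band": band,
                    "scope": "global",
                    "metric": metric,
                    "value": float(np.mean(channel_values)),
                    "family": f"{family_prefix}_global",
                }
            )
        for region in REGIONS:
            m = [i for i, r in enumerate(regions_of) if r == region]
            if m:
                rows.append(
                    base
                    | {
                        "band": band,
                        "scope": f"region:{region}",
                        "metric": metric,
                        "value": float(np.mean(channel_values[m])),
                        "family": f"{family_prefix}_region",
                    }
                )

    # spectral metrics on the broadband preprocessed signal
    spectrum = welch_psd(rec)
    for band_name, edges in config.bands.items():
        add("relative_power", band_name,
            relative_band_power(spectrum, edges), "relative_power")
    fits = fit_aperiodic_all(spectrum, fit_range=config.fit_range)
    add("exponent", "broadband", np.array([f.exponent for f in fits]), "exponent")

    # band-filtered connectivity and graph topology
    for band_name, edges in config.bands.items():
        band_rec = bandpass(rec, *edges, design="bessel3_band")
        epochs = epoch(band_rec, config.epoch_length_s, band=band_name)
        fc = band_wpli(
            epochs, edges, n_tapers=config.n_tapers,
            band_name=band_name, per_epoch=config.wpli_per_epoch,
        )
        rows.append(
            base
            | {
                "band": band_name,
                "scope": "global",
                "metric": "overall_fc",
                "value": fc.mean_connectivity(),
                "family": "overall_fc",
            }
        )
        add("nodal_strength", band_name, nodal_strength(fc), "nodal_strength",
            global_too=False)
        curves = threshold_sweep(
            fc,
            metrics=("global_efficiency", "transitivity",
                     "nodal_efficiency", "nodal_clustering"),
            thresholds=config.thresholds,
        )
        for gm in ("global_efficiency", "transitivity"):
            rows.append(
                base
                | {
                    "band": band_name,
                    "scope": "global",
                    "metric": f"auc_{gm}",
                    "value": metric_auc(curves[gm]).value,
                    "family": "graph_global",
                }
            )
        for nm in ("nodal_efficiency", "nodal_clustering"):
            auc = metric_auc(curves[nm]).value  # per channel
            for region in REGIONS:
                m = [i for i, r in enumerate(regions_of) if r == region]
                if m:
                    rows.append(
                        base
                        | {
                            "band": band_name,
                            "scope": f"region:{region}",
                            "metric": f"auc_{nm}",
                            "value": float(np.mean(auc[m])),
                            "family": f"{nm}_region",
                        }
                    )
    return rows


def _age_adjusted(study: pd.DataFrame) -> pd.DataFrame:
    """Replace each cell's values by residuals from the pooled value~age fit."""
    out = study.copy()
    for _, idx in out.groupby(["family", "band", "scope", "metric"]).groups.items():
        sub = out.loc[idx]
        out.loc[idx, "value"] = regress_out_age(
            sub["value"].to_numpy(), sub["age"].to_numpy()
        )
    return out


def run_study(config: PipelineConfig) -> StudyResults:
    """Execute the complete analysis and return all study-level tables."""
    truth = None
    if config.input_mode == "synthetic":
        recordings, truth, subjects = generate_study(config.synth)
    else:
        from .io import read_edf_study

        recordings, subjects = read_edf_study(config.edf_dir)
    ages = dict(zip(subjects.subject_id, subjects.age_years))

    rows: list[dict] = []
    for rec in recordings:
        try:
            clean = preprocess_recording(rec, config)
            rows.extend(analyze_recording(clean, config))
        except Exception as exc:  # noqa: BLE001 - annotate failing stage
            raise RuntimeError(
                f"pipeline failed on subject={rec.subject_id} "
                f"condition={rec.condition}: {exc}"
            ) from exc
    study = pd.DataFrame(rows)
    study["age"] = study["subject_id"].map(ages)

    contrasts = contrast_table(study, n_perm=config.n_perm, seed=config.seed)
    adjusted = contrast_table(
        _age_adjusted(study), n_perm=config.n_perm, seed=config.seed + 1
    )

    # age correlations for the headline metrics, pooled over conditions
    corr_rows = []
    for metric, band, scope in HEADLINE_METRICS:
        cell = study[
            (study.metric == metric) & (study.band == band) & (study.scope == scope)
        ]
        r, p = pearson_age_correlation(cell["value"].to_numpy(), cell["age"].to_numpy())
        corr_rows.append(
            {"metric": metric, "band": band, "scope": scope, "r": r, "p_raw": p,
             "n_observations": len(cell)}
        )
    age_corr = pd.DataFrame(corr_rows)
    age_corr["p_fdr"] = bh_fdr(age_corr["p_raw"].to_numpy())

    cfg_dict = asdict(config)
    manifest = {
        "package": "hypoxeeg",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": config.seed,
        "synth_seed": config.synth.seed,
        "n_perm": config.n_perm,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "config": cfg_dict,
    }

    results = StudyResults(
        study_table=study,
        contrasts=contrasts,
        contrasts_age_adjusted=adjusted,
        age_correlations=age_corr,
        manifest=manifest,
        ground_truth=truth,
    )
    if config.out_dir:
        write_results(config.out_dir, results)
    return results


def write_results(out_dir: str | Path, results: StudyResults) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results.study_table.to_csv(out / "study_table.csv", index=False)
    results.contrasts.to_csv(out / "contrasts.csv", index=False)
    results.contrasts_age_adjusted.to_csv(out / "contrasts_age_adjusted.csv", index=False)
    results.age_correlations.to_csv(out / "age_correlations.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(results.manifest, indent=1, default=str))
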