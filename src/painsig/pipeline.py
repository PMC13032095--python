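"""End-to-end orchestration: simulate -> preprocess -> index -> analyze.

`run_pipeline` is the single entry point behind the CLI; it executes the
stages in order, writes every intermediate table, and records a manifest
(config echo, seed, per-stage row counts, exclusion report, warnings) so a
rerun with the same configuration reproduces byte-identical outputs.
`analyze_cohort` is the in-memory core used both here and by simulation
studies that never touch disk.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .exceptions import ConfigurationError, EmptyCohortError, PainsigError
from .mediation import baron_kenny
from .modulation_indexes import (
    ExclusionReport,
    build_profiles,
    exclusion_filter,
    median_split,
)
from .protocol import StimulusProtocol
from .stats_core import (
    attachment_domain_matrix,
    correlation_battery,
    paired_t,
    rm_anova_gg,
    shapiro_wilk,
    wilcoxon_rank_sum,
)
from .synthetic_cohort import (
    GeneratorConfig,
    sample_traits,
    simulate_cohort,
    simulate_cohort_traces,
    traits_table,
)
from .vas_signal import epoch_means_table, preprocess, read_traces, write_traces

logger = logging.getLogger("painsig")

DEFAULT_INDEX_COLS = [
    "tai_44", "tai_46", "tai_48", "vas_low_contrast_46", "contrast_magnitude",
]

MEDIATION_MODELS = (
    # (label, X facet, M prototype, Y index)
    ("stabilization", "C5", "secure", "contrast_magnitude"),
    ("instability", "N6", "preoccupied", "contrast_magnitude"),
)


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    mode: str = "simulate+analyze"  # simulate | analyze | simulate+analyze
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)
    traces_path: str | None = None
    traits_path: str | None = None
    nrs_path: str | None = None
    exclusion_threshold: float = 3.0
    fdr_level: float = 0.05
    preprocess_window_s: float = 1.0
    output_dir: str = "painsig_run"
    seed: int | None = None
    log_level: str = "INFO"

    def __post_init__(self):
        if self.mode not in ("simulate", "analyze", "simulate+analyze"):
            raise ConfigurationError(f"unknown mode '{self.mode}'")
        if not 0 < self.fdr_level < 1:
            raise ConfigurationError("fdr_level must lie in (0, 1)")
        if self.mode != "simulate" and self.mode != "simulate+analyze":
            missing = [
                n for n, v in (
                    ("traces_path", self.traces_path),
                    ("traits_path", self.traits_path),
                    ("nrs_path", self.nrs_path),
                ) if v is None
            ]
            if missing:
                raise ConfigurationError(f"analyze mode requires {missing}")
        if self.seed is not None:
            self.generator = dataclasses.replace(self.generator, seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen_raw = raw.pop("generator", {})
        for key in ("plateau_mean", "sensitization_slope_base"):
            if key in gen_raw:
                gen_raw[key] = {float(k): float(v) for k, v in gen_raw[key].items()}
        proto_raw = raw.pop("protocol", {})
        if "sequence" in proto_raw:
            proto_raw["sequence"] = tuple(proto_raw["sequence"])
        return cls(
            generator=GeneratorConfig(**gen_raw),
            protocol=StimulusProtocol(**proto_raw),
            **raw,
        )


# ---------------------------------------------------------------------------
# In-memory analysis core
# ---------------------------------------------------------------------------

def simulate_indexes(
    config: GeneratorConfig, protocol: StimulusProtocol | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort and return (traits table, index table).

    Convenience for simulation studies: runs the generator, epochs every
    trace and derives the participant-level modulation indexes, skipping the
    inferential stages of :func:`analyze_cohort`.
    """
    protocol = protocol or StimulusProtocol()
    profs = sample_traits(config)
    traces = simulate_cohort_traces(profs, protocol, config)
    epoch_df, _ = epoch_means_table(traces, protocol)
    return traits_table(profs), build_profiles(epoch_df, protocol)

def _per_participant_epoch_matrix(epoch_df: pd.DataFrame, temp: float) -> pd.DataFrame:
    """n x 3 matrix of per-participant epoch means (trials averaged) at a temperature."""
    sub = epoch_df[epoch_df["target_temp_c"] == temp]
    return sub.groupby("participant_id")[["mean_A", "mean_B", "mean_C"]].mean()


def analyze_cohort(
    traces,
    traits: pd.DataFrame,
    nrs: pd.DataFrame,
    protocol: StimulusProtocol | None = None,
    exclusion_threshold: float = 3.0,
    fdr_level: float = 0.05,
    preprocess_window_s: float | None = 1.0,
    index_cols: list[str] | None = None,
) -> dict:
    """Run the full statistical analysis on an in-memory cohort.

    Returns a dict of tidy tables plus the exclusion report, the fitted
    mediation models and collected warnings.
    """
    protocol = protocol or StimulusProtocol()
    index_cols = index_cols or DEFAULT_INDEX_COLS
    collected_warnings: list[str] = []

    if preprocess_window_s:
        traces = [preprocess(t, window_s=preprocess_window_s) for t in traces]
    epoch_df, rejected = epoch_means_table(traces, protocol)
    if epoch_df.empty:
        raise EmptyCohortError("no usable traces after epoching")
    profiles = build_profiles(epoch_df, protocol)

    report: ExclusionReport = exclusion_filter(profiles, nrs, exclusion_threshold)
    if not report.kept_ids:
        raise EmptyCohortError("exclusion filter removed every participant")
    kept = set(report.kept_ids)
    profiles = profiles[profiles["participant_id"].isin(kept)].reset_index(drop=True)
    epoch_df = epoch_df[epoch_df["participant_id"].isin(kept)]
    traits = traits[traits["participant_id"].isin(kept)].reset_index(drop=True)

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        profiles = median_split(profiles)
        collected_warnings.extend(str(w.message) for w in wlist)

    # epoch trajectory (group means and SEs per temperature x epoch)
    traj_rows = []
    anova_rows = []
    for temp in protocol.temperatures():
        mat = _per_participant_epoch_matrix(epoch_df, temp)
        if mat.empty:
            continue
        for epoch in ("A", "B", "C"):
            col = mat[f"mean_{epoch}"]
            traj_rows.append(
                {"target_temp_c": temp, "epoch": epoch, "mean": col.mean(),
                 "se": col.std(ddof=1) / np.sqrt(len(col)), "n": len(col)}
            )
        try:
            res = rm_anova_gg(mat.to_numpy())
            anova_rows.append(
                {"target_temp_c": temp, "F": res.F, "eps_gg": res.eps_gg,
                 "df1": res.df1, "df2": res.df2, "p": res.p, "n": res.n}
            )
        except ConfigurationError as err:
            collected_warnings.append(f"rm_anova at {temp} degC skipped: {err}")

    # pairwise epoch contrasts at the 46 degC target (paired t, uncorrected)
    target_mat = _per_participant_epoch_matrix(epoch_df, protocol.contrast_target_temp_c)
    epoch_contrasts = []
    for e1, e2 in (("A", "B"), ("A", "C"), ("B", "C")):
        t, df, p = paired_t(target_mat[f"mean_{e2}"], target_mat[f"mean_{e1}"])
        epoch_contrasts.append({"contrast": f"{e2}-{e1}", "t": t, "df": df, "p": p})

    # contrast-condition paired t (high vs low)
    cc = profiles.dropna(subset=["vas_low_contrast_46", "vas_high_contrast_46"])
    t, df, p = paired_t(cc["vas_high_contrast_46"], cc["vas_low_contrast_46"])
    contrast_test = {
        "t": t, "df": df, "p": p,
        "mean_low": float(cc["vas_low_contrast_46"].mean()),
        "sd_low": float(cc["vas_low_contrast_46"].std(ddof=1)),
        "mean_high": float(cc["vas_high_contrast_46"].mean()),
        "sd_high": float(cc["vas_high_contrast_46"].std(ddof=1)),
    }

    # normality gate
    normality_rows = []
    for col in index_cols:
        vals = profiles[col].dropna().to_numpy()
        try:
            w, p_sw = shapiro_wilk(vals)
            normality_rows.append({"index": col, "W": w, "p": p_sw,
                                   "normal_at_05": p_sw >= 0.05})
        except ConfigurationError as err:
            collected_warnings.append(f"shapiro_wilk({col}) skipped: {err}")

    battery = correlation_battery(traits, profiles, index_cols, fdr_level=fdr_level)
    attach_matrix = attachment_domain_matrix(traits)

    # mediation path models
    med = traits.merge(profiles[["participant_id", "contrast_magnitude"]],
                       on="participant_id")
    mediation_models = {}
    for label, xcol, mcol, ycol in MEDIATION_MODELS:
        try:
            mediation_models[label] = baron_kenny(
                med[xcol], med[mcol], med[ycol],
                x_label=xcol, m_label=mcol, y_label=ycol,
            )
        except PainsigError as err:
            collected_warnings.append(f"mediation model '{label}' skipped: {err}")

    # sensitivity-group comparison (Wilcoxon rank sum)
    group_rows = []
    lo = profiles[profiles["sensitivity_group"] == "low"]
    hi = profiles[profiles["sensitivity_group"] == "high"]
    for col in ("tai_46", "contrast_magnitude"):
        a = hi[col].dropna().to_numpy()
        b = lo[col].dropna().to_numpy()
        if len(a) and len(b):
            res = wilcoxon_rank_sum(a, b)
            group_rows.append(
                {"index": col, "z": res["z"], "p": res["p"],
                 "mean_high": float(np.mean(a)), "sd_high": float(np.std(a, ddof=1)),
                 "mean_low": float(np.mean(b)), "sd_low": float(np.std(b, ddof=1))}
            )

    return {
        "profiles": profiles,
        "epoch_table": epoch_df,
        "rejected_traces": rejected,
        "exclusion_report": report,
        "epoch_trajectory": pd.DataFrame(traj_rows),
        "rm_anova": pd.DataFrame(anova_rows),
        "epoch_contrasts_46": pd.DataFrame(epoch_contrasts),
        "contrast_paired_t": contrast_test,
        "normality": pd.DataFrame(normality_rows),
        "correlations": battery,
        "attachment_domain_matrix": attach_matrix,
        "mediation": mediation_models,
        "group_comparison": pd.DataFrame(group_rows),
        "warnings": collected_warnings,
    }


# ---------------------------------------------------------------------------
# Disk-backed run
# ---------------------------------------------------------------------------

def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write all outputs plus a manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "painsig_version": _version,
        "mode": config.mode,
        "seed": config.generator.seed,
        "exclusion_threshold": config.exclusion_threshold,
        "fdr_level": config.fdr_level,
        "stages": {},
        "warnings": [],
    }
    gen_dict = config.generator.to_dict()
    gen_dict["plateau_mean"] = {str(k): v for k, v in gen_dict["plateau_mean"].items()}
    gen_dict["sensitization_slope_base"] = {
        str(k): v for k, v in gen_dict["sensitization_slope_base"].items()
    }
    manifest["generator_config"] = gen_dict
    manifest["protocol_sequence"] = list(config.protocol.sequence)

    def stage(name):
        logger.info("stage: %s", name)
        manifest["stages"][name] = {"started": time.time()}
        return name

    def done(name, **counts):
        st = manifest["stages"][name]
        st["elapsed_s"] = round(time.time() - st.pop("started"), 3)
        st.update(counts)

    try:
        if config.mode in ("simulate", "simulate+analyze"):
            name = stage("simulate")
            profiles, traces, nrs = simulate_cohort(config.generator, config.protocol)
            traits = traits_table(profiles)
            _write_csv(traits, out / "traits.csv")
            write_traces(traces, out / "traces.csv")
            _write_csv(nrs, out / "nrs.csv")
            config.generator.to_json(out / "generator_config.json")
            done(name, n_participants=len(profiles), n_traces=len(traces))
        else:
            name = stage("load")
            traces = read_traces(config.traces_path, config.protocol)
            traits = pd.read_csv(config.traits_path)
            traits["participant_id"] = traits["participant_id"].astype(str)
            nrs = pd.read_csv(config.nrs_path)
            nrs["participant_id"] = nrs["participant_id"].astype(str)
            done(name, n_traces=len(traces), n_participants=len(traits))

        if config.mode in ("analyze", "simulate+analyze"):
            name = stage("analyze")
            results = analyze_cohort(
                traces, traits, nrs,
                protocol=config.protocol,
                exclusion_threshold=config.exclusion_threshold,
                fdr_level=config.fdr_level,
                preprocess_window_s=config.preprocess_window_s,
            )
            _write_csv(results["profiles"], out / "indexes.csv")
            _write_csv(results["epoch_table"], out / "epoch_means.csv")
            _write_csv(results["epoch_trajectory"], out / "epoch_trajectory.csv")
            _write_csv(results["rm_anova"], out / "rm_anova.csv")
            _write_csv(results["epoch_contrasts_46"], out / "epoch_contrasts_46.csv")
            _write_csv(results["normality"], out / "normality.csv")
            _write_csv(results["correlations"], out / "correlations.csv")
            _write_csv(results["attachment_domain_matrix"],
                       out / "attachment_domain_matrix.csv")
            _write_csv(results["group_comparison"], out / "group_comparison.csv")
            with open(out / "contrast_paired_t.json", "w") as fh:
                json.dump(results["contrast_paired_t"], fh, indent=2, sort_keys=True)
            with open(out / "mediation.json", "w") as fh:
                json.dump({k: m.to_dict() for k, m in results["mediation"].items()},
                          fh, indent=2, sort_keys=True)
            with open(out / "exclusion_report.json", "w") as fh:
                json.dump(results["exclusion_report"].to_dict(), fh, indent=2,
                          sort_keys=True)
            rep = results["exclusion_report"]
            manifest["exclusion"] = {
                "n_input": rep.n_input, "n_kept": len(rep.kept_ids),
                "n_excluded": len(rep.excluded),
            }
            manifest["warnings"].extend(results["warnings"])
            manifest["n_rejected_traces"] = len(results["rejected_traces"])
            done(name, n_kept=len(rep.kept_ids), n_excluded=len(rep.excluded))
    except Exception as err:
        failed = next(
            (n for n, st in manifest["stages"].items() if "started" in st), "unknown"
        )
        manifest["failed_stage"] = failed
        manifest["error"] = str(err)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        raise

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


def make_report(run_dir) -> dict[str, pd.DataFrame]:
    """Collect the study-shaped summary tables of a completed run.

    Missing stage outputs are listed as absent, never fabricated.
    """
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise EmptyCohortError(f"{run_dir}: no manifest.json; not a completed run")
    tables = {}
    absent = []
    for name, fname in [
        ("epoch_trajectory", "epoch_trajectory.csv"),
        ("rm_anova", "rm_anova.csv"),
        ("epoch_contrasts_46", "epoch_contrasts_46.csv"),
        ("correlations", "correlations.csv"),
        ("attachment_domain_matrix", "attachment_domain_matrix.csv"),
        ("group_comparison", "group_comparison.csv"),
        ("indexes", "indexes.csv"),
    ]:
        path = run_dir / fname
        if path.exists():
            tables[name] = pd.read_csv(path)
        else:
            absent.append(name)
    for name, fname in [("mediation", "mediation.json"),
                        ("contrast_paired_t", "contrast_paired_t.json"),
                        ("exclusion_report", "exclusion_report.json")]:
        path = run_dir / fname
        if path.exists():
            with open(path) as fh:
                tables[name] = json.load(fh)
        else:
            absent.append(name)
    if not tables:
        raise EmptyCohortError(f"{run_dir}: no stage outputs found")
    tables["absent"] = absent
    return tables
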