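"""Stage drivers joining classification, coding, CA and GLM inference.

These functions operate on plain DataFrames (the CSV schemas in
:mod:`vertpattern.io`), so the CLI subcommands and the analysis scripts can
compose them through files while tests call them in memory.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ca as ca_mod
from . import glm as glm_mod
from .columns import VertebralColumn, classify_column
from .malformations import (
    GERM_LAYERS,
    N_AFFECTED_BANDS,
    ORGAN_SYSTEMS,
    PROCESSES,
    Finding,
    SystemStatus,
    TermEntry,
    code_subject,
    n_affected_band,
)

DEFAULT_AGE_EDGES = (13.0, 20.0, 28.0, 40.0, 92.0)


def classify_columns(columns: list[VertebralColumn]) -> pd.DataFrame:
    """Classify every evaluable column; one row per subject."""
    rows = []
    for col in columns:
        if col.quality.value != "evaluable":
            continue
        res = classify_column(col)
        rows.append(
            {
                "subject_id": res.subject_id,
                "pattern": res.pattern.value,
                "severity": res.severity,
                "ct_shift": int(res.shifts.ct),
                "tl_shift": int(res.shifts.tl),
                "ls_shift": int(res.shifts.ls),
                "ct_direction": res.shifts.ct_direction.value,
                "tl_direction": res.shifts.tl_direction.value,
                "cervical": res.counts.cervical,
                "thoracic": res.counts.thoracic,
                "lumbar": res.counts.lumbar,
                "presacral": res.counts.presacral,
                "extreme": int(res.extreme),
                "segmentation_suspect": int(res.counts.segmentation_suspect),
            }
        )
    cols = ["subject_id", "pattern", "severity", "ct_shift", "tl_shift", "ls_shift",
            "ct_direction", "tl_direction", "cervical", "thoracic", "lumbar",
            "presacral", "extreme", "segmentation_suspect"]
    return pd.DataFrame(rows, columns=cols)


def code_findings_table(
    per_subject: dict[str, tuple[list[Finding], dict[str, bool]]],
    coding_map: dict[str, TermEntry] | None = None,
) -> pd.DataFrame:
    """Code every subject's findings; one row per subject."""
    rows = []
    for sid in sorted(per_subject):
        findings, availability = per_subject[sid]
        rec = code_subject(findings, coding_map, availability, subject_id=sid)
        row = {"subject_id": sid}
        for sys in ORGAN_SYSTEMS:
            row[f"status_{sys}"] = rec.primary_flags[sys].value
        row["n_affected"] = rec.n_systems_affected
        row["band"] = n_affected_band(rec)
        row["fully_non_available"] = int(rec.fully_non_available)
        for layer in GERM_LAYERS:
            row[f"layer_{layer}"] = int(layer in rec.germ_layers)
        for proc in PROCESSES:
            row[f"process_{proc}"] = int(proc in rec.processes)
        rows.append(row)
    cols = ["subject_id", *[f"status_{s}" for s in ORGAN_SYSTEMS], "n_affected", "band",
            "fully_non_available", *[f"layer_{l}" for l in GERM_LAYERS],
            *[f"process_{p}" for p in PROCESSES]]
    return pd.DataFrame(rows, columns=cols)


def _records_from_coded(coded: pd.DataFrame) -> dict:
    from .malformations import MalformationRecord

    records = {}
    for _, row in coded.iterrows():
        flags = {s: SystemStatus(row[f"status_{s}"]) for s in ORGAN_SYSTEMS}
        records[str(row["subject_id"])] = MalformationRecord(
            subject_id=str(row["subject_id"]), primary_flags=flags
        )
    return records


def outcome_vectors(merged: pd.DataFrame) -> dict[str, np.ndarray]:
    """Binary (NaN = non-available) outcome per organ system, plus the
    no-malformation indicator and germ-layer / process indicators."""
    out: dict[str, np.ndarray] = {}
    for sys in ORGAN_SYSTEMS:
        status = merged[f"status_{sys}"]
        vec = np.where(
            status == SystemStatus.NON_AVAILABLE.value,
            np.nan,
            (status == SystemStatus.AFFECTED.value).astype(float),
        )
        out[sys] = vec
    fully_na = merged["fully_non_available"].astype(bool).to_numpy()
    no_mal = np.where(fully_na, np.nan, (merged["n_affected"] == 0).astype(float))
    out["No-Mal"] = no_mal
    for layer in GERM_LAYERS:
        out[f"layer_{layer}"] = np.where(
            fully_na, np.nan, merged[f"layer_{layer}"].astype(float)
        )
    for proc in PROCESSES:
        out[f"process_{proc}"] = np.where(
            fully_na, np.nan, merged[f"process_{proc}"].astype(float)
        )
    return out


@dataclass
class AnalysisReport:
    """Everything the analyze stage produces, as plain tables."""

    glm_table: pd.DataFrame
    comparisons: pd.DataFrame
    interaction: glm_mod.InteractionLRT | None
    trends: pd.DataFrame
    ca_results: dict[str, ca_mod.CAResult]
    contingency: dict[str, pd.DataFrame]
    covariate_tests: pd.DataFrame
    failures: list[str] = field(default_factory=list)

    def summary_text(self, seed: int | None = None, cfg_hash: str = "") -> str:
        lines = [
            f"vertpattern analysis summary (seed={seed}, config={cfg_hash})",
            "",
            "Severity-association GLMs (logit link, severity slope):",
            self.glm_table.to_string(index=False),
            "",
        ]
        for name, res in self.ca_results.items():
            pe = ", ".join(f"{x:.1f} %" for x in res.percent_explained)
            lines.append(f"CA [{name}]: total inertia {res.total_inertia:.4f}; "
                         f"explained per dim: {pe}")
        if self.interaction is not None:
            it = self.interaction
            lines.append(
                f"Germ-layer × severity interaction LRT: chi2={it.chi2:.3f}, "
                f"df={it.df}, p={it.p:.3f}"
            )
        if len(self.trends):
            lines += ["", "Frequency trends over n-affected bands:",
                      self.trends.to_string(index=False)]
        if self.failures:
            lines += ["", "FAILED STAGES:", *self.failures]
        return "\n".join(lines) + "\n"


def analyze(
    classified: pd.DataFrame,
    coded: pd.DataFrame,
    truth: pd.DataFrame | None = None,
    age_edges: tuple[float, ...] = DEFAULT_AGE_EDGES,
    include_covariates: bool = True,
) -> AnalysisReport:
    """Run both contingency groupings, CA, all association GLMs and trends.

    ``truth`` (optional) supplies sex and gestational age for the factor
    covariates and the pattern × covariate χ² checks.
    """
    merged = classified.merge(coded, on="subject_id", how="inner")
    if merged.empty:
        raise ValueError("classified and coded tables share no subjects")
    severity = merged["severity"].to_numpy(dtype=float)
    failures: list[str] = []

    sex = age_band = None
    if truth is not None and include_covariates:
        demo = truth[["subject_id", "sex", "gestational_age_weeks"]]
        merged = merged.merge(demo, on="subject_id", how="left")
        sex = merged["sex"].fillna("unknown").to_numpy()
        age_band = pd.cut(
            merged["gestational_age_weeks"], bins=list(age_edges), include_lowest=True
        ).astype(str).to_numpy()

    outcomes = outcome_vectors(merged)

    glm_rows = []
    fits: dict[str, glm_mod.GLMFit] = {}
    for name, vec in outcomes.items():
        try:
            fit = glm_mod.fit_severity_glm(vec, severity, sex=sex, age_band=age_band)
        except glm_mod.GLMError as err:
            failures.append(f"GLM[{name}]: {err}")
            continue
        fits[name] = fit
        try:
            disp = fit.dispersion_ratio
        except glm_mod.GLMError:
            disp = np.nan
        glm_rows.append(
            {
                "outcome": name,
                "n": fit.n,
                "events": int(np.nansum(vec)),
                "slope": fit.coef_of("severity"),
                "se": fit.se_of("severity"),
                "p": fit.p_of("severity"),
                "dispersion": disp,
                "converged": fit.converged,
            }
        )
    glm_table = pd.DataFrame(
        glm_rows,
        columns=["outcome", "n", "events", "slope", "se", "p", "dispersion", "converged"],
    )

    comp_rows = []
    for a, b in itertools.combinations(PROCESSES, 2):
        ka, kb = f"process_{a}", f"process_{b}"
        if ka not in fits or kb not in fits:
            continue
        try:
            comp = glm_mod.compare_slopes(outcomes[ka], outcomes[kb], severity, labels=(a, b))
        except glm_mod.GLMError as err:
            failures.append(f"compare[{a},{b}]: {err}")
            continue
        comp_rows.append(
            {"group_a": a, "group_b": b, "slope_a": comp.slope_a, "slope_b": comp.slope_b,
             "difference": comp.difference, "t": comp.statistic, "p": comp.p}
        )
    comparisons = pd.DataFrame(
        comp_rows, columns=["group_a", "group_b", "slope_a", "slope_b", "difference", "t", "p"]
    )

    interaction = None
    try:
        interaction = glm_mod.interaction_lrt(
            {l: outcomes[f"layer_{l}"] for l in GERM_LAYERS}, severity
        )
    except glm_mod.GLMError as err:
        failures.append(f"germ-layer interaction: {err}")

    # frequency of the regular and of the most abnormal pattern per band
    trend_rows = []
    band_freqs: dict[str, list[float]] = {"R": [], "CT_TL_LS": []}
    bands_present = [b for b in N_AFFECTED_BANDS if (merged["band"].astype(str) == b).any()]
    for b in bands_present:
        sel = merged[merged["band"].astype(str) == b]
        for pat in band_freqs:
            band_freqs[pat].append((sel["pattern"] == pat).mean())
    for pat, freqs in band_freqs.items():
        try:
            tr = glm_mod.freq_trend(np.array(freqs))
            trend_rows.append({"pattern": pat, "r": tr.r, "p": tr.p, "n_points": tr.n_points})
        except glm_mod.GLMError as err:
            failures.append(f"trend[{pat}]: {err}")
    trends = pd.DataFrame(trend_rows, columns=["pattern", "r", "p", "n_points"])

    patterns_by_sid = dict(zip(merged["subject_id"].astype(str), merged["pattern"]))
    records = _records_from_coded(coded)
    ca_results: dict[str, ca_mod.CAResult] = {}
    contingency: dict[str, pd.DataFrame] = {}
    for grouping in ("four_level", "eight_level"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                table = ca_mod.build_contingency(patterns_by_sid, records, grouping)
            contingency[grouping] = table
            ca_results[grouping] = ca_mod.orient_result(
                ca_mod.correspondence_analysis(table)
            )
        except ca_mod.CAError as err:
            failures.append(f"CA[{grouping}]: {err}")

    cov_rows = []
    if truth is not None:
        demo = truth.set_index("subject_id")
        pats = merged.set_index("subject_id")["pattern"]
        sex_vals = demo.loc[pats.index, "sex"]
        ga_vals = demo.loc[pats.index, "gestational_age_weeks"]
        ga_bands = pd.cut(ga_vals, bins=list(age_edges), include_lowest=True).astype(str)
        for name, cov in (("sex", sex_vals), ("age_band", ga_bands)):
            try:
                res = glm_mod.pattern_covariate_chisq(pats.to_numpy(), cov.to_numpy())
                cov_rows.append({"covariate": name, "chi2": res.chi2, "df": res.df,
                                 "p": res.p, "warning": res.warning or ""})
            except ValueError as err:
                failures.append(f"chisq[{name}]: {err}")
    covariate_tests = pd.DataFrame(cov_rows, columns=["covariate", "chi2", "df", "p", "warning"])

    return AnalysisReport(
        glm_table=glm_table,
        comparisons=comparisons,
        interaction=interaction,
        trends=trends,
        ca_results=ca_results,
        contingency=contingency,
        covariate_tests=covariate_tests,
        failures=failures,
    )


def write_report(
    report: AnalysisReport,
    out_dir: str | Path,
    seed: int | None = None,
    config: object = None,
) -> Path:
    """Write the report bundle (TSVs + plain-text summary) to a directory."""
    from .io import config_hash, write_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.glm_table.to_csv(out / "glm_associations.tsv", sep="\t", index=False)
    report.comparisons.to_csv(out / "slope_comparisons.tsv", sep="\t", index=False)
    report.trends.to_csv(out / "frequency_trends.tsv", sep="\t", index=False)
    report.covariate_tests.to_csv(out / "covariate_chisq.tsv", sep="\t", index=False)
    for name, table in report.contingency.items():
        write_table(table, out / f"contingency_{name}.csv", f"contingency-{name}",
                    seed=seed, config=config, index=True)
    for name, res in report.ca_results.items():
        inertia = pd.DataFrame(
            {"dim": np.arange(1, res.n_dims + 1),
             "principal_inertia": res.principal_inertias,
             "percent_explained": res.percent_explained}
        )
        inertia.to_csv(out / f"ca_{name}_inertia.tsv", sep="\t", index=False)
        res.coords_frame().to_csv(out / f"ca_{name}_coords.tsv", sep="\t")
    if report.interaction is not None:
        it = report.interaction
        pd.DataFrame(
            [{"test": "germ_layer_x_severity", "chi2": it.chi2, "df": it.df, "p": it.p}]
        ).to_csv(out / "interaction_lrt.tsv", sep="\t", index=False)
    summary = report.summary_text(seed=seed, cfg_hash=config_hash(config) if config else "")
    (out / "summary.txt").write_text(summary, encoding="utf-8")
    if report.failures:
        (out / "failure_manifest.txt").write_text("\n".join(report.failures) + "\n",
                                                  encoding="utf-8")
    return out
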