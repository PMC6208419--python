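"""Study table I/O, pipeline configuration and end-to-end orchestration.

The on-disk interchange format is a UTF-8 comma-delimited long table with one
row per (subject, ROI, time) measurement:

    subject_id,group_id,particle_id,route,roi,time_h,value,value_kind,excluded,exclusion_reason

``value`` is %ID/g for tissue ROIs and %ID for bladder/whole-body rows
(``value_kind`` distinguishes them); ``excluded`` marks subjects dropped from
analysis with the reason recorded.  Writing then reading a table is the
identity on a canonical ordering, so reports regenerate byte-identically.

:func:`run_pipeline` drives the full analysis: per subject x ROI variant
selection and fitting, group parameter summaries, bioavailability fractions
where a particle was dosed by both routes, power-law size correlations per
organ class, and requested group statistics.  Failures are fail-soft: each
unit is fitted independently, failures are recorded, and every input row is
accounted for in the report as fitted, excluded, not modelled, or failed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import analysis as pka
from .fitting import (
    ConcentrationSeries,
    FitError,
    GuessError,
    ModelFit,
    ROITaxonomy,
    fit_group,
    fit_series,
    select_variant,
)
from .models import ContractError, DomainError, ModelVariant
from .synthetic import SyntheticStudy

__all__ = [
    "STUDY_COLUMNS",
    "ParseError",
    "PipelineConfig",
    "ReportBundle",
    "read_study",
    "write_study",
    "series_to_table",
    "table_to_series",
    "run_pipeline",
]

STUDY_COLUMNS = ("subject_id", "group_id", "particle_id", "route", "roi",
                 "time_h", "value", "value_kind", "excluded",
                 "exclusion_reason")


class ParseError(ValueError):
    """A study table violates the schema; the message names the row."""


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

def _canonical(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["exclusion_reason"] = out["exclusion_reason"].fillna("").astype(str)
    out["excluded"] = out["excluded"].astype(bool)
    out = out.sort_values(["group_id", "subject_id", "roi", "time_h"],
                          kind="stable").reset_index(drop=True)
    return out[list(STUDY_COLUMNS)]


def _validate_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in STUDY_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"missing required columns: {missing}")
    for i, row in df.iterrows():
        if row["route"] not in ("iv", "ip"):
            raise ParseError(f"row {i}: bad route {row['route']!r}")
        if row["value_kind"] not in ("concentration", "activity"):
            raise ParseError(f"row {i}: bad value_kind {row['value_kind']!r}")
        if not np.isfinite(row["time_h"]) or row["time_h"] < 0:
            raise ParseError(f"row {i}: time_h must be >= 0, got {row['time_h']}")
        if not np.isfinite(row["value"]) or row["value"] < 0:
            raise ParseError(f"row {i}: value must be >= 0, got {row['value']}")
    dupes = df.duplicated(subset=["subject_id", "roi", "time_h"])
    if dupes.any():
        first = int(np.nonzero(dupes.values)[0][0])
        raise ParseError(f"row {first}: duplicate (subject, roi, time)")
    return _canonical(df)


def read_study(path) -> pd.DataFrame:
    """Read and validate a long-format study table from CSV."""
    df = pd.read_csv(path, dtype={"subject_id": str, "group_id": str,
                                  "particle_id": str, "roi": str},
                     keep_default_na=False, na_values=[""])
    missing = [c for c in STUDY_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"missing required columns: {missing}")
    df["excluded"] = df["excluded"].map(
        lambda x: str(x).strip().lower() in ("true", "1", "yes"))
    df["time_h"] = pd.to_numeric(df["time_h"], errors="coerce")
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    return _validate_table(df)


def write_study(df: pd.DataFrame, path) -> None:
    """Write a study table in canonical order (round-trips with read_study)."""
    out = _canonical(df)
    out.to_csv(path, index=False)  # default float repr round-trips exactly


def series_to_table(series: Sequence[ConcentrationSeries]) -> pd.DataFrame:
    """Flatten series objects into the long study-table format."""
    rows = []
    for s in series:
        pid = s.group_id.rsplit("_", 1)[0]
        for t, v in zip(s.times, s.values):
            rows.append({"subject_id": s.subject_id, "group_id": s.group_id,
                         "particle_id": pid, "route": s.route, "roi": s.roi,
                         "time_h": float(t), "value": float(v),
                         "value_kind": s.value_kind,
                         "excluded": bool(s.excluded),
                         "exclusion_reason": s.exclusion_reason})
    return _canonical(pd.DataFrame(rows))


def table_to_series(df: pd.DataFrame) -> list[ConcentrationSeries]:
    """Group table rows back into per subject x ROI series."""
    out = []
    for (subj, roi), grp in df.groupby(["subject_id", "roi"], sort=True):
        grp = grp.sort_values("time_h")
        out.append(ConcentrationSeries(
            subject_id=str(subj), group_id=str(grp["group_id"].iloc[0]),
            roi=str(roi), route=str(grp["route"].iloc[0]),
            times=grp["time_h"].to_numpy(float),
            values=grp["value"].to_numpy(float),
            value_kind=str(grp["value_kind"].iloc[0]),
            excluded=bool(grp["excluded"].any()),
            exclusion_reason=str(grp["exclusion_reason"].iloc[0])))
    return out


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything the pipeline needs beyond the data itself.

    Unknown keys in a config file are rejected so that typos fail loudly.
    """

    seed: int = 0
    taxonomy_overrides: dict[str, str] = field(default_factory=dict)
    fit_mode: str = "per_subject"          # or "pooled"
    weights: Optional[str] = None          # None | "1/value^2"
    auc_horizon: float = 24.0
    variant_overrides: dict[str, str] = field(default_factory=dict)  # roi -> variant
    sar_size_column: str = "core_diameter_nm"   # design column used as the size
    sar_method: str = "loglog_ols"
    stats_requests: list[dict] = field(default_factory=list)
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.fit_mode not in ("per_subject", "pooled"):
            raise ContractError(f"bad fit_mode {self.fit_mode!r}")
        if self.auc_horizon <= 0:
            raise ContractError("auc_horizon must be > 0")
        for roi, v in self.variant_overrides.items():
            ModelVariant(v)  # raises on unknown variant names

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ContractError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ParseError("config file must contain a mapping")
        return cls.from_dict(data)

    def taxonomy(self) -> ROITaxonomy:
        return ROITaxonomy().with_overrides(self.taxonomy_overrides)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class ReportBundle:
    """All pipeline outputs as data frames plus a JSON-able stats report."""

    fits: pd.DataFrame            # one row per subject x ROI x parameter
    pk: pd.DataFrame              # one row per subject x ROI PK summary
    group_summaries: pd.DataFrame
    bioavailability: pd.DataFrame
    sar: pd.DataFrame
    stats: dict
    records: pd.DataFrame         # per input row: disposition of that row
    model_fits: dict[tuple[str, str], ModelFit] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "fits": self.fits.to_dict(orient="records"),
            "pk": self.pk.to_dict(orient="records"),
            "group_summaries": self.group_summaries.to_dict(orient="records"),
            "bioavailability": self.bioavailability.to_dict(orient="records"),
            "sar": self.sar.to_dict(orient="records"),
            "stats": self.stats,
            "record_accounting": self.records.groupby("status")
                                             .size().to_dict(),
        }
        return json.dumps(payload, sort_keys=True, indent=1,
                          default=float)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("fits", "pk", "group_summaries", "bioavailability",
                     "sar", "records"):
            getattr(self, name).to_csv(outdir / f"{name}.csv", index=False,
                                       float_format="%.10g")
        (outdir / "report.json").write_text(self.to_json())


def _float_or_none(x) -> Optional[float]:
    return None if x is None else float(x)


def run_pipeline(table: pd.DataFrame, config: PipelineConfig,
                 design: Optional[pd.DataFrame] = None) -> ReportBundle:
    """Run the full analysis on a validated study table.

    ``design`` (particle_id, core_diameter_nm, ...) enables the power-law
    size correlations; without it the SAR table is empty.  Deterministic for
    a fixed table and config.
    """
    table = _validate_table(table)
    tax = config.taxonomy()
    series = table_to_series(table)

    # group series by (group, roi) so the data-driven variant rules can see
    # the whole group
    by_unit: dict[tuple[str, str], list[ConcentrationSeries]] = {}
    for s in series:
        by_unit.setdefault((s.group_id, s.roi), []).append(s)

    fit_rows, pk_rows, record_rows = [], [], []
    group_rows = []
    model_fits: dict[tuple[str, str], ModelFit] = {}
    auc_by = {}  # (group_id, roi) -> list of per-subject AUCs

    for (group_id, roi), members in sorted(by_unit.items()):
        route = members[0].route
        active = [m for m in members if not m.excluded]
        for m in members:
            if m.excluded:
                record_rows.append({"group_id": group_id, "subject_id":
                                    m.subject_id, "roi": roi,
                                    "status": "excluded",
                                    "detail": m.exclusion_reason})
        try:
            roi_class = tax.class_of(roi)
        except ContractError as exc:
            for m in active:
                record_rows.append({"group_id": group_id,
                                    "subject_id": m.subject_id, "roi": roi,
                                    "status": "failed", "detail": str(exc)})
            continue

        if roi_class == "bladder":
            for m in active:
                record_rows.append({"group_id": group_id,
                                    "subject_id": m.subject_id, "roi": roi,
                                    "status": "not_modeled",
                                    "detail": "no kinetic model is fitted to "
                                              "bladder data"})
            continue
        if not active:
            continue

        override = config.variant_overrides.get(roi)
        try:
            variant = select_variant(
                roi_class, route, active,
                override=ModelVariant(override) if override else None)
        except ContractError as exc:
            for m in active:
                record_rows.append({"group_id": group_id,
                                    "subject_id": m.subject_id, "roi": roi,
                                    "status": "failed", "detail": str(exc)})
            continue

        targets = active
        if roi_class == "whole_body":
            # model the cumulative excreted activity, not retention
            targets = [pka.total_excreted_series(m) for m in active]

        unit_fits = []
        for m in targets:
            try:
                fit = fit_series(m, variant, weights=config.weights)
            except (FitError, GuessError, ContractError, DomainError) as exc:
                record_rows.append({"group_id": group_id,
                                    "subject_id": m.subject_id, "roi": roi,
                                    "status": "failed", "detail": str(exc)})
                continue
            unit_fits.append(fit)
            model_fits[(m.subject_id, roi)] = fit
            record_rows.append({"group_id": group_id,
                                "subject_id": m.subject_id, "roi": roi,
                                "status": "fitted",
                                "detail": "; ".join(fit.warnings)})
            for name in variant.param_names:
                fit_rows.append({
                    "group_id": group_id, "subject_id": m.subject_id,
                    "roi": roi, "route": route, "variant": variant.value,
                    "parameter": name, "estimate": fit.params.get(name),
                    "stderr": _float_or_none(fit.standard_errors.get(name)),
                    "rss": fit.rss, "dof": fit.dof, "n_obs": fit.n_obs,
                    "converged": fit.converged})
            summary = pka.summarize_fit(fit, horizon=config.auc_horizon)
            pk_rows.append({
                "group_id": group_id, "subject_id": m.subject_id, "roi": roi,
                "route": route, "variant": variant.value,
                "AUC_0_24": summary.AUC_0_24,
                "t_half": _float_or_none(summary.t_half),
                "k_in": _float_or_none(summary.k_in),
                "k_out": _float_or_none(summary.k_out),
                "C_max": summary.C_max,
                "t_max": _float_or_none(summary.t_max),
                "A": summary.A, "notes": summary.notes})
            auc_by.setdefault((group_id, roi), []).append(summary.AUC_0_24)

        # group summary across successfully fitted subjects
        excluded_ids = tuple(sorted(m.subject_id for m in members if m.excluded))
        if unit_fits:
            for name in variant.param_names:
                vals = np.array([f.params.get(name) for f in unit_fits])
                group_rows.append({
                    "group_id": group_id, "roi": roi, "route": route,
                    "variant": variant.value, "parameter": name,
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                    "n": len(vals),
                    "excluded_subjects": ";".join(excluded_ids)})

    fits_df = pd.DataFrame(fit_rows)
    pk_df = pd.DataFrame(pk_rows)
    groups_df = pd.DataFrame(group_rows)
    records_df = pd.DataFrame(record_rows)

    # ------------------------------------------------------------------ F
    bio_rows = []
    particles = sorted(table["particle_id"].unique())
    for pid in particles:
        auc_iv = auc_by.get((f"{pid}_iv", "heart"))
        auc_ip = auc_by.get((f"{pid}_ip", "heart"))
        if auc_iv and auc_ip:
            F = pka.bioavailability_fraction(float(np.mean(auc_ip)),
                                             float(np.mean(auc_iv)))
            bio_rows.append({"particle_id": pid, "F_percent": F,
                             "auc_ip": float(np.mean(auc_ip)),
                             "auc_iv": float(np.mean(auc_iv)),
                             "dose_ip": 1.0, "dose_iv": 1.0})
    bio_df = pd.DataFrame(bio_rows)

    # ------------------------------------------------------------- SAR fits
    sar_rows = []
    if design is not None and not pk_df.empty:
        sizes_of = dict(zip(design["particle_id"],
                            design[config.sar_size_column]))
        for route in sorted(table["route"].unique()):
            for roi in sorted(table["roi"].unique()):
                try:
                    roi_class = tax.class_of(roi)
                except ContractError:
                    continue
                if roi_class in ("bladder", "whole_body"):
                    continue
                pts = []
                for pid in particles:
                    aucs = auc_by.get((f"{pid}_{route}", roi))
                    if aucs and pid in sizes_of:
                        pts.append((float(sizes_of[pid]),
                                    float(np.mean(aucs))))
                if len(pts) < 3:
                    continue
                sizes, aucs = zip(*sorted(pts))
                try:
                    sar = pka.power_law_fit(sizes, aucs,
                                            organ_class=roi_class,
                                            method=config.sar_method)
                except ContractError:
                    continue
                lo, hi = sar.exponent_ci()
                sar_rows.append({
                    "roi": roi, "organ_class": roi_class, "route": route,
                    "lambda": sar.lam, "exponent": sar.exponent, "n": sar.n,
                    "se_exponent": sar.se_exponent,
                    "ci95_low": lo, "ci95_high": hi,
                    "r_squared": sar.r_squared, "n_points": sar.n_points})
    sar_df = pd.DataFrame(sar_rows)

    # ------------------------------------------------------------ statistics
    stats_out = {}
    for req in config.stats_requests:
        name = req.get("name") or f"{req.get('parameter')}_{req.get('roi')}"
        param, roi = req.get("parameter"), req.get("roi")
        routes = req.get("routes")
        sel = fits_df[(fits_df["parameter"] == param)
                      & (fits_df["roi"] == roi)] if not fits_df.empty \
            else pd.DataFrame()
        if routes is not None and not sel.empty:
            sel = sel[sel["route"].isin(routes)]
        groups = {g: sub["estimate"].to_list()
                  for g, sub in sel.groupby("group_id")
                  if len(sub) >= 2}
        if len(groups) < 2:
            stats_out[name] = {"error": "fewer than 2 usable groups"}
            continue
        pairs = [tuple(p) for p in req.get("t_test_pairs", [])]
        pairs = [p for p in pairs if p[0] in groups and p[1] in groups]
        report = pka.compare_groups(groups, t_test_pairs=pairs,
                                    alpha=config.alpha)
        stats_out[name] = report.to_dict()

    return ReportBundle(fits=fits_df, pk=pk_df, group_summaries=groups_df,
                        bioavailability=bio_df, sar=sar_df, stats=stats_out,
                        records=records_df, model_fits=model_fits)


def run_pipeline_on_study(study: SyntheticStudy,
                          config: Optional[PipelineConfig] = None
                          ) -> ReportBundle:
    """Convenience wrapper: flatten a synthetic study and run the pipeline."""
    config = config or PipelineConfig(seed=study.config.seed)
    return run_pipeline(series_to_table(study.series), config,
                        design=study.design)
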