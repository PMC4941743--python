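"""End-to-end orchestration: images -> D -> species means -> statistics.

A run takes a directory of trace images plus a specimen table (or, in
summaries-only mode, a pre-computed species summary table), an optional
newick tree with a FAD/LAD table, and produces a report holding the
per-specimen D table, species summaries, the tribe-level Welch
comparison with normality/variance checks, per-clade and unified PGLS
fits, single-trait phylogenetic signal, and the between-tribe slope
comparison.  Individual bad images are skipped with a log entry;
structural problems (no usable specimens, too little tree/data overlap)
abort the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .boxcount import BoxCountConfig, estimate_D
from .comparative_stats import (
    ComparativeDataset,
    RegressionFit,
    compare_slopes,
    distribution_checks,
    gls_fit,
    lambda_signal,
    pooled_from_species,
    profile_lambda,
    welch_t,
)
from .phylo import load_ranges, phylo_covariance, read_tree, time_calibrate
from .trace_io import (
    SpeciesSummary,
    SpecimenRecord,
    load_specimens,
    normalize_taxon,
    read_trace,
    summaries_to_frame,
    summarize_species,
)

logger = logging.getLogger(__name__)

IMAGE_SUFFIXES = (".png", ".tif", ".tiff")


@dataclass
class RunConfig:
    """Everything a pipeline run needs; serializable for provenance."""

    images_dir: str | None = None
    specimen_table: str | None = None
    summaries_table: str | None = None  # summaries-only mode
    tree_file: str | None = None
    ranges_file: str | None = None
    output_dir: str | None = None
    # box counting
    sizes: Sequence[int] = (2, 3, 4, 6, 8, 12, 16, 32, 64)
    threshold: float = 0.5
    dark_foreground: bool = True
    # calibration
    vartime: float = 1.0
    add_term: bool = True
    # analysis
    clades: Sequence[str] = ("Hipparionini", "Equini", "Equinae")
    lambda_mode: str = "ml"  # "ml" or "fixed"
    lambda_fixed: float = 0.0
    include_indeterminate: bool = True  # keep "sp." / indet. taxa
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vartime <= 0:
            raise ValueError("vartime must be > 0")
        if self.lambda_mode not in ("ml", "fixed"):
            raise ValueError("lambda_mode must be 'ml' or 'fixed'")

    def digest(self) -> str:
        payload = {k: list(v) if isinstance(v, tuple) else v
                   for k, v in dataclasses.asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunReport:
    """All tables a run produces, plus provenance."""

    specimen_D: pd.DataFrame
    species_summary: pd.DataFrame
    tribe_comparison: dict
    regressions: pd.DataFrame
    signal: pd.DataFrame
    provenance: dict
    slope_comparison: dict | None = None
    distribution: dict | None = None

    def to_json(self) -> str:
        def _default(o):
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, pd.DataFrame):
                return o.to_dict(orient="records")
            return str(o)

        return json.dumps(
            {
                "specimen_D": self.specimen_D,
                "species_summary": self.species_summary,
                "tribe_comparison": self.tribe_comparison,
                "regressions": self.regressions,
                "signal": self.signal,
                "slope_comparison": self.slope_comparison,
                "distribution": self.distribution,
                "provenance": self.provenance,
            },
            default=_default,
            indent=2,
        )


def _is_indeterminate(taxon: str) -> bool:
    t = taxon.lower()
    return t.endswith(" sp.") or t.endswith(" spp.") or "indet" in t


def compute_specimen_D(
    records: list[SpecimenRecord], images_dir: str | Path, cfg: RunConfig
) -> pd.DataFrame:
    """Estimate D for each specimen's image; bad images are skipped."""
    images_dir = Path(images_dir)
    rows = []
    for rec in records:
        path = None
        for suf in IMAGE_SUFFIXES:
            cand = images_dir / f"{rec.specimen_id}{suf}"
            if cand.exists():
                path = cand
                break
        if path is None:
            logger.warning("no image for specimen %s; skipped", rec.specimen_id)
            continue
        try:
            trace = read_trace(
                path, threshold=cfg.threshold, dark_foreground=cfg.dark_foreground
            )
            est = estimate_D(trace, BoxCountConfig(sizes=cfg.sizes))
        except Exception as exc:  # fail soft per specimen
            logger.warning("specimen %s failed: %s", rec.specimen_id, exc)
            continue
        rec.D = est.D
        rows.append(
            {
                "specimen_id": rec.specimen_id,
                "taxon": rec.taxon,
                "tribe": rec.tribe,
                "D": est.D,
                "fit_r2": est.fit_r2,
                "n_sizes": len(est.series.sizes),
            }
        )
    return pd.DataFrame(rows)


def _summaries_from_table(path: str | Path) -> list[SpeciesSummary]:
    df = pd.read_csv(path)
    out = []
    for r in df.itertuples(index=False):
        out.append(
            SpeciesSummary(
                taxon=normalize_taxon(r.taxon),
                tribe=r.tribe,
                n_D=int(r.n_D),
                mean_D=float(r.mean_D),
                sd_D=None if pd.isna(r.sd_D) else float(r.sd_D),
                n_area=int(r.n_area),
                mean_area=None if pd.isna(r.mean_area) else float(r.mean_area),
                sd_area=None if pd.isna(r.sd_area) else float(r.sd_area),
            )
        )
    return out


def _clade_dataset(
    summaries: list[SpeciesSummary], clade: str, tip_labels: set[str],
    include_indeterminate: bool,
) -> ComparativeDataset | None:
    rows = [
        s
        for s in summaries
        if (clade == "Equinae" or s.tribe == clade)
        and s.n_area > 0
        and (include_indeterminate or not _is_indeterminate(s.taxon))
    ]
    rows = [s for s in rows if s.taxon in tip_labels]
    if len(rows) < 3:
        return None
    return ComparativeDataset(
        taxa=[s.taxon for s in rows],
        x=np.array([s.mean_area for s in rows]),
        y=np.array([s.mean_D for s in rows]),
    )


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis described by ``config``."""
    cfg = config
    specimen_df = pd.DataFrame()
    distribution = None

    if cfg.summaries_table:
        summaries = _summaries_from_table(cfg.summaries_table)
    else:
        if not (cfg.images_dir and cfg.specimen_table):
            raise ValueError(
                "need images_dir + specimen_table, or a summaries_table"
            )
        records = load_specimens(cfg.specimen_table)
        precomputed = all(r.D is not None for r in records) and records
        if precomputed:
            specimen_df = pd.DataFrame(
                [
                    {
                        "specimen_id": r.specimen_id,
                        "taxon": r.taxon,
                        "tribe": r.tribe,
                        "D": r.D,
                    }
                    for r in records
                ]
            )
        else:
            specimen_df = compute_specimen_D(records, cfg.images_dir, cfg)
            records = [r for r in records if r.D is not None]
        if not len(records):
            raise ValueError("no usable specimens")
        summaries = summarize_species(records)
        by_tribe = {
            tribe: [r.D for r in records if r.tribe == tribe]
            for tribe in ("Hipparionini", "Equini")
        }
        by_tribe = {k: v for k, v in by_tribe.items() if len(v) >= 3}
        if len(by_tribe) == 2:
            distribution = distribution_checks(by_tribe)

    # tribe-level comparison of specimen D, from pooled species summaries
    tribe_comparison: dict = {}
    try:
        g_hip = pooled_from_species(summaries, "Hipparionini")
        g_eq = pooled_from_species(summaries, "Equini")
        t, df_w, p = welch_t(g_eq, g_hip)
        tribe_comparison = {
            "t": t,
            "df": df_w,
            "p": p,
            "equini_mean": g_eq.mean,
            "hipparionini_mean": g_hip.mean,
            "equini_n": g_eq.n,
            "hipparionini_n": g_hip.n,
            "significant": p < cfg.alpha,
        }
    except ValueError as exc:
        logger.warning("tribe comparison unavailable: %s", exc)

    # phylogenetic analyses
    reg_rows, sig_rows = [], []
    slope_comparison = None
    if cfg.tree_file and cfg.ranges_file:
        tree = read_tree(cfg.tree_file)
        ranges = load_ranges(cfg.ranges_file)
        dated = time_calibrate(tree, ranges, vartime=cfg.vartime, add_term=cfg.add_term)
        V = phylo_covariance(dated)
        tips = set(V.taxa)
        matched = [s for s in summaries if s.taxon in tips]
        if len(matched) < 3:
            raise ValueError("tree/data taxon overlap < 3")
        dropped = [s.taxon for s in summaries if s.taxon not in tips]
        if dropped:
            logger.warning("taxa absent from tree dropped: %s", dropped)

        fits: dict[str, RegressionFit] = {}
        for clade in cfg.clades:
            data = _clade_dataset(
                summaries, clade, tips, cfg.include_indeterminate
            )
            if data is None:
                logger.warning("clade %s: fewer than 3 usable species", clade)
                continue
            if cfg.lambda_mode == "ml":
                fit = profile_lambda(data, V)
            else:
                fit = gls_fit(data, V, lam=cfg.lambda_fixed)
            fits[clade] = fit
            reg_rows.append(
                {
                    "clade": clade,
                    "lambda": fit.lambda_hat,
                    "lambda_ci_low": fit.lambda_ci[0],
                    "lambda_ci_high": fit.lambda_ci[1],
                    "slope": fit.slope,
                    "se": fit.se_slope,
                    "t": fit.t_slope,
                    "p": fit.p_slope,
                    "r2_multiple": fit.r2_multiple,
                    "r2_adjusted": fit.r2_adjusted,
                    "n": fit.n,
                }
            )
            # single-trait signal (intercept-only lambda), per trait
            for trait_name in ("D", "area"):
                vals = {
                    s.taxon: (s.mean_D if trait_name == "D" else s.mean_area)
                    for s in matched
                    if (clade == "Equinae" or s.tribe == clade)
                    and (trait_name == "D" or s.n_area > 0)
                    and (cfg.include_indeterminate or not _is_indeterminate(s.taxon))
                }
                if len(vals) < 3:
                    continue
                try:
                    lam_hat, ci = lambda_signal(vals, V)
                except ValueError as exc:
                    logger.warning(
                        "signal %s/%s unavailable: %s", clade, trait_name, exc
                    )
                    continue
                sig_rows.append(
                    {
                        "clade": clade,
                        "trait": trait_name,
                        "lambda": lam_hat,
                        "ci_low": ci[0],
                        "ci_high": ci[1],
                        "n": len(vals),
                    }
                )
        if "Hipparionini" in fits and "Equini" in fits:
            t, df_s, p = compare_slopes(fits["Hipparionini"], fits["Equini"])
            slope_comparison = {
                "t": t,
                "df": df_s,
                "p": p,
                "significant": p < cfg.alpha,
            }

    provenance = {
        "package_version": __version__,
        "config": dataclasses.asdict(cfg),
        "config_digest": cfg.digest(),
        "seed": cfg.seed,
    }
    report = RunReport(
        specimen_D=specimen_df,
        species_summary=summaries_to_frame(summaries),
        tribe_comparison=tribe_comparison,
        regressions=pd.DataFrame(reg_rows),
        signal=pd.DataFrame(sig_rows),
        provenance=provenance,
        slope_comparison=slope_comparison,
        distribution=distribution,
    )
    if cfg.output_dir:
        outdir = Path(cfg.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        if len(report.specimen_D):
            report.specimen_D.to_csv(outdir / "specimen_D.csv", index=False)
        report.species_summary.to_csv(outdir / "species_summary.csv", index=False)
        if len(report.regressions):
            report.regressions.to_csv(outdir / "regressions.csv", index=False)
        if len(report.signal):
            report.signal.to_csv(outdir / "signal.csv", index=False)
        (outdir / "report.json").write_text(report.to_json())
    return report
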