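"""Full-pipeline orchestration: one call from record files to report tables.

``evaluate_study`` runs the four evaluation stages in memory and returns a
bundle of DataFrames (segmentation accuracy, classification accuracy, kappa
summaries per group and per granularity level, portion-size error summaries,
per-nutrient agreement fits with limits-of-agreement curves and CV tables).
``run_pipeline`` wraps it with file I/O: it reads JSON-lines record files and
an optional link/grade file, writes each table as CSV plus a JSON summary,
and is idempotent for a fixed seed.  No report-layer arithmetic: every cell
comes from a module operation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .agreement import cv_summary, fit_agreement, limits_of_agreement
from .classification import (
    classification_accuracy,
    confusion_table,
    grade_match,
    kappa_summary,
    sensitivity_specificity,
    uniform_kappa,
)
from .portion import group_error_summary, weight_errors
from .records import NUTRIENTS, Record, read_records
from .segmentation import (
    LinkedPair,
    MatchTable,
    SegmentationCoding,
    link_segments,
    segmentation_accuracy,
)
from .taxonomy import FoodTaxonomy, load_fixture_taxonomy, load_taxonomy

__all__ = ["RunConfig", "evaluate_study", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    ref_path: str
    app_path: str
    out_dir: str
    links_path: Optional[str] = None  # CSV: record_id, ref_idx, app_idx, grade, flags
    taxonomy_path: Optional[str] = None  # default: bundled fixture
    exclusions: list = field(default_factory=list)  # [(record_id, ref_idx), ...]
    bootstrap_B: int = 2000
    seed: int = 0

    def validate(self) -> None:
        for p in (self.ref_path, self.app_path, self.links_path, self.taxonomy_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def _match_table_from_links(links: pd.DataFrame, ref: Sequence[Record]) -> MatchTable:
    table = MatchTable()
    linked_ref = set()
    for row in links.itertuples(index=False):
        if row.grade == "I" or row.ref_idx < 0:
            table.intrusions.append((str(row.record_id), int(row.app_idx)))
        else:
            table.links.append(LinkedPair(str(row.record_id), int(row.ref_idx), int(row.app_idx)))
            linked_ref.add((str(row.record_id), int(row.ref_idx)))
    for rec in ref:
        for i in range(rec.n_segments):
            if (rec.record_id, i) not in linked_ref:
                table.omissions.append((rec.record_id, i))
    return table


def _grade_links(
    table: MatchTable, ref: Sequence[Record], app: Sequence[Record], tax: FoodTaxonomy
) -> pd.DataFrame:
    """Grade automatically linked pairs (no analyst flags: C never assigned)."""
    ref_by_id = {r.record_id: r for r in ref}
    app_by_id = {r.record_id: r for r in app}
    rows = []
    for link in table.links:
        g = grade_match(
            ref_by_id[link.record_id].segments[link.ref_idx],
            app_by_id[link.record_id].segments[link.app_idx],
            flags=(),
            tax=tax,
        )
        rows.append(
            {"record_id": link.record_id, "ref_idx": link.ref_idx,
             "app_idx": link.app_idx, "grade": g.value, "flags": ""}
        )
    return pd.DataFrame(rows, columns=["record_id", "ref_idx", "app_idx", "grade", "flags"])


def evaluate_study(
    ref: Sequence[Record],
    app: Sequence[Record],
    tax: Optional[FoodTaxonomy] = None,
    links: Optional[pd.DataFrame] = None,
    exclusions: Sequence[tuple[str, int]] = (),
    bootstrap_B: int = 2000,
    seed: int = 0,
) -> dict:
    """Run segmentation, classification, portion and agreement stages.

    ``links`` (record_id/ref_idx/app_idx/grade/flags, intrusions as grade "I")
    bypasses automatic linking and carries analyst grades; without it, pairs
    are linked by taxonomy-distance assignment and graded without analyst
    flags (so no close matches).  Returns a dict of DataFrames and fit
    objects; all bootstrap randomness derives from ``seed``.
    """
    tax = tax if tax is not None else load_fixture_taxonomy()
    rng = np.random.default_rng(seed)

    if links is not None:
        table = _match_table_from_links(links, ref)
        grades = links[links["grade"] != "I"].copy()
    else:
        table = link_segments(ref, app, tax)
        grades = _grade_links(table, ref, app, tax)

    # --- stage 1: segmentation -------------------------------------------
    coding = SegmentationCoding.from_match_table(table, ref)
    seg_table = segmentation_accuracy(coding)

    # --- stage 2: classification -----------------------------------------
    stratum_of = {r.record_id: r.stratum() for r in ref}
    grades = grades.copy()
    grades["record_type"] = grades["record_id"].map(stratum_of)
    cls_table = classification_accuracy(grades, by="record_type")

    ref_by_id = {r.record_id: r for r in ref}
    app_by_id = {r.record_id: r for r in app}
    type_pairs = [
        (ref_by_id[r.record_id].segments[int(r.ref_idx)].food_type,
         app_by_id[r.record_id].segments[int(r.app_idx)].food_type)
        for r in grades.itertuples(index=False)
    ]
    grade_vec = grades["grade"].to_numpy()

    # label-crosstab kappas at the three granularities (Table 4 analogue),
    # plus the by-definition agreement (E/C are type-correct; E/C/F group-correct)
    level_rows = []
    for level, by_def_ok in (
        ("category", None),
        ("group", np.isin(grade_vec, ["E", "C", "F"])),
        ("type", np.isin(grade_vec, ["E", "C"])),
    ):
        conf = confusion_table(type_pairs, level, tax)
        indicators = [
            int(tax.level_label(a, level) == tax.level_label(b, level)) for a, b in type_pairs
        ]
        ks = kappa_summary(conf, indicators, B=bootstrap_B, seed=rng)
        row = {
            "level": level, "q": ks.q, "n": ks.n,
            "cohen_kappa": ks.cohen_kappa, "cohen_se": ks.cohen_se,
            "uniform_kappa": ks.uniform_kappa,
            "uniform_lo": ks.uniform_ci[0], "uniform_hi": ks.uniform_ci[1],
        }
        if by_def_ok is not None:
            row["uniform_kappa_by_grade"] = uniform_kappa(float(by_def_ok.mean()), ks.q)
        level_rows.append(row)
    global_kappa = pd.DataFrame(level_rows).set_index("level")

    # per-food-group one-vs-rest table (Table 3 analogue)
    group_conf = confusion_table(type_pairs, "group", tax)
    group_rows = []
    for label in group_conf.table.index:
        tp, fn, fp, tn = group_conf.binary_for(label)
        if tp + fn + fp == 0:
            continue  # group absent from both sides
        ss = sensitivity_specificity(tp, fn, fp, tn)
        binary_ind = [
            int((a == label) == (b == label))
            for a, b in ((tax.group_of(x), tax.group_of(y)) for x, y in type_pairs)
        ]
        po = float(np.mean(binary_ind))
        lo, hi = np.nan, np.nan
        try:
            from .classification import cohen_kappa as _ck, uniform_kappa_ci

            ck, se = _ck(np.array([[tp, fn], [fp, tn]]))
            lo, hi = uniform_kappa_ci(binary_ind, q=2, B=bootstrap_B, seed=rng)
        except ValueError:
            ck, se = np.nan, np.nan
        group_rows.append(
            {"group": label, "tp": tp, "fn": fn, "fp": fp, "tn": tn,
             "cohen_kappa": ck, "cohen_se": se,
             "uniform_kappa": uniform_kappa(po, 2), "uniform_lo": lo, "uniform_hi": hi,
             "sensitivity": ss.sensitivity, "sens_lo": ss.sens_ci[0], "sens_hi": ss.sens_ci[1],
             "specificity": ss.specificity, "spec_lo": ss.spec_ci[0], "spec_hi": ss.spec_ci[1]}
        )
    group_kappa = pd.DataFrame(group_rows).set_index("group")

    # --- stage 3: portion size -------------------------------------------
    errors = weight_errors(table, grades, ref, app, exclusions=exclusions)
    portion_tables = {
        level: group_error_summary(errors, level, tax) for level in ("type", "group", "category")
    }

    # --- stage 4: energy & macronutrient agreement ------------------------
    excluded_records = {rid for rid, _ in exclusions}
    kept = [r for r in ref if r.record_id not in excluded_records]
    fits, loa_curves, cv_rows = {}, {}, []
    for nutrient in NUTRIENTS:
        x = np.array([r.total_nutrients().model_dump()[nutrient] for r in kept])
        y = np.array(
            [app_by_id[r.record_id].total_nutrients().model_dump()[nutrient] for r in kept]
        )
        if np.ptp(x) == 0:
            logger.warning("nutrient %s constant in reference; agreement fit skipped", nutrient)
            continue
        fit = fit_agreement(x, y, nutrient=nutrient)
        fits[nutrient] = fit
        grid = np.linspace(x.min(), x.max(), 50)
        loa_curves[nutrient] = limits_of_agreement(fit, grid)
        kinds = np.array([r.record_kind for r in kept])
        for stratum, mask in (
            ("all", np.ones(len(kept), dtype=bool)),
            ("foods", kinds == "food"),
            ("beverages", kinds == "beverage"),
        ):
            if mask.sum() == 0:
                continue
            try:
                cv = cv_summary(fit, x[mask], stratum=stratum)
            except ValueError:
                continue
            cv_rows.append(cv.__dict__)
    fit_table = pd.DataFrame(
        [
            {"nutrient": k, "alpha": f.alpha, "beta": f.beta,
             "alpha_se": f.alpha_se, "beta_se": f.beta_se,
             "s0": f.s0, "s1": f.s1, "n": f.n}
            for k, f in fits.items()
        ]
    ).set_index("nutrient")
    cv_table = pd.DataFrame(cv_rows)

    return {
        "match_table": table,
        "grades": grades,
        "segmentation": seg_table,
        "classification": cls_table,
        "group_kappa": group_kappa,
        "global_kappa": global_kappa,
        "weight_errors": errors,
        "portion": portion_tables,
        "agreement_fits": fits,
        "agreement_table": fit_table,
        "loa_curves": loa_curves,
        "cv_table": cv_table,
    }


def run_pipeline(cfg: RunConfig) -> dict:
    """File-level pipeline: read records (+links), evaluate, write the bundle."""
    cfg.validate()
    ref = read_records(cfg.ref_path)
    app = read_records(cfg.app_path)
    links = pd.read_csv(cfg.links_path) if cfg.links_path else None
    tax = (
        load_fixture_taxonomy() if cfg.taxonomy_path is None else load_taxonomy(cfg.taxonomy_path)
    )
    results = evaluate_study(
        ref, app, tax=tax, links=links,
        exclusions=[tuple(e) for e in cfg.exclusions],
        bootstrap_B=cfg.bootstrap_B, seed=cfg.seed,
    )

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results["segmentation"].to_csv(out / "segmentation_accuracy.csv")
    results["classification"].to_csv(out / "classification_accuracy.csv")
    results["group_kappa"].to_csv(out / "group_kappa.csv")
    results["global_kappa"].to_csv(out / "global_kappa.csv")
    for level, tbl in results["portion"].items():
        tbl.to_csv(out / f"portion_error_{level}.csv")
    results["weight_errors"].to_csv(out / "weight_errors.csv", index=False)
    results["agreement_table"].to_csv(out / "agreement_fits.csv")
    for nutrient, curve in results["loa_curves"].items():
        curve.to_csv(out / f"loa_{nutrient}.csv", index=False)
    results["cv_table"].to_csv(out / "cv_summary.csv", index=False)
    results["match_table"].to_frame().to_csv(out / "match_table.csv", index=False)

    cfg_hash = hashlib.sha256(
        json.dumps(cfg.__dict__, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    summary = {
        "schema_version": 1,
        "dieteval_version": __version__,
        "seed": cfg.seed,
        "config_sha256": cfg_hash,
        "n_ref_records": len(ref),
        "n_app_records": len(app),
        "segmentation_total": results["segmentation"].loc["total"].to_dict(),
        "classification_total": results["classification"].loc["total"].to_dict(),
        "global_uniform_kappa": results["global_kappa"]["uniform_kappa"].to_dict(),
    }
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    logger.info("report bundle written to %s (config %s)", out, cfg_hash)
    results["summary"] = summary
    return results
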