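"""Full-pipeline orchestration and machine-readable reports.

``run_full_analysis`` replays the complete analysis on the packaged study
table (or any TSV in the same schema): HWE per study, overall pooling per
genetic model with the heterogeneity gate, the four subgroup
stratifications with forced random effects, five-model multiplicity
adjustment, publication-bias tests, leave-one-out sensitivity, and trial
sequential analysis on the allelic model.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .association import hwe_test
from .bias import begg_test, egger_test, funnel_data, leave_one_out
from .core_data import StudyDataset, fixture_table1, read_study_table
from .genetic_models import GENETIC_MODELS, dataset_contrasts
from .multiplicity import SUBGROUP_AXES, adjust_pvalues, subgroup_analysis
from .pooling import PoolResult, pool_auto
from .tsa import TSAConfig, accumulation_order, cumulative_z_curve


def _pool_dict(r: PoolResult) -> dict[str, Any]:
    return {
        "k": r.k,
        "pooling": r.pooling,
        "or": round(r.pooled_or, 4),
        "ci_low": round(r.ci_low, 4),
        "ci_high": round(r.ci_high, 4),
        "z": round(r.z, 4),
        "p": r.p,
        "q": round(r.q, 4),
        "p_het": r.p_het,
        "i2": round(r.i2, 2),
        "tau2": round(r.tau2, 6),
        "n_cases": r.n_cases,
        "n_controls": r.n_controls,
    }


def _analyse_dataset(ds: StudyDataset, tsa_cfg: TSAConfig) -> dict[str, Any]:
    out: dict[str, Any] = {"snp": ds.snp, "k": len(ds)}

    out["hwe"] = {
        s.study_id: dataclasses.asdict(hwe_test(s.controls)) for s in ds
    }

    overall: dict[str, Any] = {}
    for model in GENETIC_MODELS:
        tables = [t for t in dataset_contrasts(ds, model) if not t.excluded]
        if not tables:
            continue
        overall[model.value] = _pool_dict(pool_auto(tables))
    raws = [overall[m]["p"] for m in overall]
    adj = adjust_pvalues(raws, family_size=len(GENETIC_MODELS))
    for i, m in enumerate(overall):
        overall[m]["p_bonferroni"] = adj.bonferroni[i]
        overall[m]["p_fdr"] = adj.bh_fdr[i]
    out["overall"] = overall

    out["subgroups"] = {}
    for axis in SUBGROUP_AXES:
        cells = subgroup_analysis(ds, axis)
        out["subgroups"][axis] = {
            level: {
                "models": {m.value: _pool_dict(r) for m, r in cell.results.items()},
                "p_bonferroni": list(cell.adjusted.bonferroni),
                "p_fdr": list(cell.adjusted.bh_fdr),
            }
            for level, cell in cells.items()
        }

    allelic = [
        t for t in dataset_contrasts(ds, GENETIC_MODELS[0]) if not t.excluded
    ]
    from .pooling import pool_random_dl  # effects for bias tests
    effects = pool_random_dl(allelic).per_study
    if len(effects) >= 3:
        eg, bg = egger_test(effects), begg_test(effects)
        out["bias"] = {
            "egger_intercept": eg.egger_intercept,
            "egger_p": eg.egger_p,
            "begg_tau": bg.begg_tau,
            "begg_p": bg.begg_p,
        }
    out["funnel"] = funnel_data(effects).to_dict(orient="records")

    loo = leave_one_out(allelic)
    out["leave_one_out"] = {
        sid: {"or": round(r.pooled_or, 4), "ci_low": round(r.ci_low, 4),
              "ci_high": round(r.ci_high, 4)}
        for sid, r in loo.omitted.items()
    }

    ordered = accumulation_order(ds)
    ordered_tables = [
        t
        for t in dataset_contrasts(StudyDataset(ds.snp, ordered), GENETIC_MODELS[0])
        if not t.excluded
    ]
    tsa = cumulative_z_curve(ordered_tables, tsa_cfg)
    out["tsa"] = {
        "ris": tsa.ris,
        "pooling": tsa.pooling,
        "conventional_crossed": tsa.conventional_crossed,
        "boundary_crossed": tsa.boundary_crossed,
        "ris_reached": tsa.ris_reached,
        "steps": [dataclasses.asdict(s) for s in tsa.steps],
    }
    return out


def run_full_analysis(
    source: str = "fixture",
    snps: list[str] | None = None,
    tsa_cfg: TSAConfig | None = None,
) -> dict[str, Any]:
    """Run the whole pipeline; ``source`` is "fixture" or a TSV path."""
    datasets = fixture_table1() if source == "fixture" else read_study_table(source)
    if snps:
        datasets = [d for d in datasets if d.snp in snps]
    if not datasets:
        raise ValueError("no datasets selected")
    cfg = tsa_cfg or TSAConfig()
    return {
        "provenance": {"source": source, "package_version": __version__},
        "snps": {ds.snp: _analyse_dataset(ds, cfg) for ds in datasets},
    }


def table2_frame(report: dict[str, Any]) -> pd.DataFrame:
    """Tidy per-(snp, stratum, model) summary table of the report."""
    rows = []
    for snp, block in report["snps"].items():
        for m, r in block["overall"].items():
            rows.append({"snp": snp, "stratum": "overall", "level": "overall",
                         "model": m, **r})
        for axis, levels in block["subgroups"].items():
            for level, cell in levels.items():
                for i, (m, r) in enumerate(cell["models"].items()):
                    rows.append({
                        "snp": snp, "stratum": axis, "level": level, "model": m,
                        **r,
                        "p_bonferroni": cell["p_bonferroni"][i],
                        "p_fdr": cell["p_fdr"][i],
                    })
    return pd.DataFrame(rows)


def write_report(report: dict[str, Any], out_dir: str | Path) -> None:
    """Serialize report.json plus tidy CSV side-tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    table2_frame(report).to_csv(out / "table2.csv", index=False)
    tsa_rows, funnel_rows, loo_rows = [], [], []
    for snp, block in report["snps"].items():
        for s in block["tsa"]["steps"]:
            tsa_rows.append({"snp": snp, **s})
        for r in block["funnel"]:
            funnel_rows.append({"snp": snp, **r})
        for sid, r in block["leave_one_out"].items():
            loo_rows.append({"snp": snp, "omitted": sid, **r})
    pd.DataFrame(tsa_rows).to_csv(out / "tsa_steps.csv", index=False)
    pd.DataFrame(funnel_rows).to_csv(out / "funnel.csv", index=False)
    pd.DataFrame(loo_rows).to_csv(out / "loo.csv", index=False)
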