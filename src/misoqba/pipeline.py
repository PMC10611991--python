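"""End-to-end analysis pipeline: load or generate a cohort, derive the
endpoints, tabulate, test, bias-adjust, and write a report bundle.

All deterministic stages are byte-identical across reruns with the same
configuration; stochastic stages (generator, Monte Carlo bias analysis)
are seeded and their seeds recorded in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from importlib.metadata import version as _pkg_version

from .records import read_records, write_records, write_data_dictionary
from .endpoints import derive_frame, effectiveness_counts, EFFECTIVENESS_CLASSES
from .descriptives import proportion_ci, tabulate, proportion_expelled_within
from .inference import chi2_independence, fisher_exact, table_from_frame
from .qba import BiasParameters, default_bias_parameters, run_qba, with_seed
from .synth import CohortConfig, generate

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Exactly one of ``input_records`` (a participant CSV) or
    ``generator_config`` (a :class:`CohortConfig`) must be supplied."""

    output_dir: Path
    input_records: Optional[Path] = None
    generator_config: Optional[CohortConfig] = None
    ci_method: str = "wilson"
    alpha: float = 0.05
    bias_params: Optional[BiasParameters] = None
    seed: int = 0
    qba_n_iter: int = 50_000

    def __post_init__(self):
        if (self.input_records is None) == (self.generator_config is None):
            raise ValueError(
                "supply exactly one of input_records or generator_config")


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle into ``output_dir``.

    Returns a dict of the headline results (endpoints, test p-values, the
    bias-adjusted estimate) that is also written to ``summary.json``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        _version = _pkg_version("misoqba")
    except Exception:
        _version = "unknown"
    manifest = {"version": _version, "seed": config.seed,
                "ci_method": config.ci_method, "alpha": config.alpha}

    if config.input_records is not None:
        records = read_records(config.input_records)  # full-pass validation
        manifest["input"] = str(config.input_records)
        manifest["input_sha256"] = _sha256(config.input_records)
    else:
        gcfg = config.generator_config
        records, truth = generate(gcfg)
        write_records(records, out / "records.csv")
        truth.to_csv(out / "truth.csv", index=False)
        manifest["generator_seed"] = gcfg.seed
        manifest["n_generated"] = gcfg.n
    write_data_dictionary(out / "data_dictionary.csv")

    frame = derive_frame(records)
    n = len(records)

    # ---- effectiveness endpoints (the Table 2 analog) ------------------
    endpoints = []
    tables = {}
    for tp, col in (("fu1", "eff_fu1"), ("fu2", "eff_fu2"),
                    ("last_recorded", "eff_last")):
        counts = effectiveness_counts(records, tp)
        denom = sum(counts.values())
        res = proportion_ci(counts["complete_no_procedure"], denom,
                            alpha=config.alpha, method=config.ci_method)
        endpoints.append({"timepoint": tp, "numerator": res.numerator,
                          "denominator": res.denominator,
                          "percent": res.percent,
                          "ci_low": res.ci_low, "ci_high": res.ci_high,
                          "method": res.method})
        tables[f"effectiveness_{tp}"] = tabulate(
            frame[frame[col].notna()], col, strata="duration_weeks",
            row_order=EFFECTIVENESS_CLASSES)
    # subgroup endpoints by regimen at last recorded follow-up
    for reg in ("endorsed_3x800", "other"):
        sub = frame[frame["regimen"] == reg]
        num = int((sub["eff_last"] == "complete_no_procedure").sum())
        res = proportion_ci(num, len(sub), alpha=config.alpha,
                            method=config.ci_method)
        endpoints.append({"timepoint": f"last_recorded[{reg}]",
                          "numerator": num, "denominator": len(sub),
                          "percent": res.percent, "ci_low": res.ci_low,
                          "ci_high": res.ci_high, "method": res.method})
    pd.DataFrame(endpoints).to_csv(out / "endpoints.csv", index=False)

    # ---- descriptive tables (Table 1/3/4 analogs) ----------------------
    for name, var, strata in (
            ("baseline_site", "site", "regimen"),
            ("baseline_age", "age_group", "regimen"),
            ("baseline_education", "education", "regimen"),
            ("baseline_duration", "duration_weeks", "regimen"),
            ("safety_warning_sign", "warning_sign", "duration_weeks"),
            ("safety_adverse_event", "adverse_event", "duration_weeks"),
            ("care_facility", "care_facility", "warning_sign")):
        tables[name] = tabulate(frame, var, strata=strata)
    with (out / "tables.txt").open("w") as fh:
        for name, tab in tables.items():
            fh.write(f"== {name} ==\n{tab.to_text()}\n\n")
    for name, tab in tables.items():
        tab.to_frame().to_csv(out / f"table_{name}.csv", index=False)

    expelled = proportion_expelled_within(records, 24.0, alpha=config.alpha,
                                          method=config.ci_method)

    # ---- inference -----------------------------------------------------
    test_rows = []
    care_tab = table_from_frame(frame, "warning_sign", "sought_care")
    for fn in (chi2_independence, fisher_exact):
        try:
            res = fn(care_tab)
        except ValueError as exc:
            log.warning("care-seeking test skipped: %s", exc)
            continue
        test_rows.append({"comparison": "sought_care_by_warning_sign",
                          "method": res.method, "statistic": res.statistic,
                          "df": res.df, "p_value": res.p_value})
    pd.DataFrame(test_rows).to_csv(out / "tests.csv", index=False)

    # ---- quantitative bias analysis ------------------------------------
    params = config.bias_params or default_bias_parameters(
        seed=config.seed, n_iter=config.qba_n_iter)
    params = with_seed(params, config.seed)
    followed = frame[frame["fu2_attended"]]
    observed_pos = int((followed["eff_fu2"] == "complete_no_procedure").sum())
    qba_res = run_qba(observed_pos, len(followed), n, params)
    pd.DataFrame([{
        "point_estimate": qba_res.point_estimate,
        "sim_low": qba_res.sim_low, "sim_high": qba_res.sim_high,
        "n_kept": qba_res.n_kept, "n_discarded": qba_res.n_discarded,
        "n_iter": qba_res.n_iter, "seed": qba_res.seed,
    }]).to_csv(out / "qba.csv", index=False)
    log.info("QBA: %s", qba_res)

    summary = {
        "n": n,
        "endpoints": endpoints,
        "expelled_within_24h": {"numerator": expelled.numerator,
                                "denominator": expelled.denominator,
                                "percent": expelled.percent},
        "tests": test_rows,
        "qba": {"point_estimate": qba_res.point_estimate,
                "sim_low": qba_res.sim_low, "sim_high": qba_res.sim_high,
                "n_discarded": qba_res.n_discarded},
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return summary
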