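"""Cross-model agreement and the mechanism verdict.

The pipeline's lines of evidence combine into one of three verdicts:

* ``MCAR-not-rejected`` — Little's test does not reject at level alpha;
  nothing in the data contradicts MCAR.
* ``consistent-with-MAR`` — Little's test rejects MCAR *and* at least one
  classifier finds missingness predictable from observed variables (an
  out-of-bag AUC above its no-signal band, or a significant GEE predictor).
* ``inconclusive`` — MCAR is rejected but neither classifier finds an
  observed-variable signal.  MNAR is never asserted: a missingness model
  built from observed variables cannot distinguish MAR from MNAR, it can
  only find evidence *consistent with* MAR.

The no-signal band edge for the forest's out-of-bag AUC defaults to 0.55,
the upper edge of its sampling variability on data with MCAR deletion at
study-like sizes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .classifiers import (
    DEFAULT_PREDICTORS,
    GEEFit,
    RFFit,
    fit_rf,
    forward_select,
    select_corstr,
)
from .data_model import LongitudinalDataset, read_long_csv, to_wide, write_long_csv
from .little import LittleResult, little_test
from .patterns import enumerate_patterns, missingness_rates
from .synthetic import GeneratorConfig, generate

logger = logging.getLogger(__name__)

#: Upper edge of the forest's no-signal out-of-bag AUC band.
DEFAULT_AUC_BAND = 0.55


@dataclass
class AgreementTable:
    """2x2 cross-tabulation of the two classifiers' night-level predictions."""

    both_present: int  # RF 0, GEE 0
    rf_only_missing: int  # RF 1, GEE 0
    gee_only_missing: int  # RF 0, GEE 1
    both_missing: int  # RF 1, GEE 1

    @property
    def total(self) -> int:
        return (
            self.both_present
            + self.rf_only_missing
            + self.gee_only_missing
            + self.both_missing
        )

    @property
    def n_agree(self) -> int:
        return self.both_present + self.both_missing

    @property
    def agreement(self) -> float:
        return self.n_agree / self.total

    @property
    def agreement_percent(self) -> int:
        return int(round(100.0 * self.agreement))


def compare_predictions(rf_pred, gee_pred, keys=None) -> AgreementTable:
    """Cross-tabulate two aligned binary prediction vectors.

    If ``keys`` (e.g. (participant, night) tuples) are given for both
    vectors they must match exactly, otherwise alignment is positional and
    only lengths are checked.
    """
    if keys is not None:
        k_rf, k_gee = keys
        if list(k_rf) != list(k_gee):
            raise ValueError("prediction vectors are not aligned on (participant, night)")
    rf = np.asarray(rf_pred).astype(int)
    gee = np.asarray(gee_pred).astype(int)
    if rf.shape != gee.shape:
        raise ValueError(f"length mismatch: {rf.shape} vs {gee.shape}")
    return AgreementTable(
        both_present=int(((rf == 0) & (gee == 0)).sum()),
        rf_only_missing=int(((rf == 1) & (gee == 0)).sum()),
        gee_only_missing=int(((rf == 0) & (gee == 1)).sum()),
        both_missing=int(((rf == 1) & (gee == 1)).sum()),
    )


@dataclass
class MechanismDiagnosis:
    """Combined verdict over Little's test and the two classifiers."""

    little_p: float
    rf_oob_auc: float
    gee_significant_terms: list
    verdict: str  # MCAR-not-rejected | consistent-with-MAR | inconclusive
    narrative: str
    alpha: float = 0.05
    auc_band: float = DEFAULT_AUC_BAND


def diagnose(
    little: LittleResult,
    rf: RFFit,
    gee: GEEFit,
    alpha: float = 0.05,
    auc_band: float = DEFAULT_AUC_BAND,
) -> MechanismDiagnosis:
    """Combine the three lines of evidence into a mechanism verdict.

    A degenerate Little result (df = 0, complete data in the wide table)
    yields an ``inconclusive`` verdict with an explanation.
    """
    sig_terms = [
        t for t, p in gee.model.p_values_.items() if t != "const" and p < alpha
    ]
    lines = []
    if little.df == 0 or not np.isfinite(little.p_value):
        verdict = "inconclusive"
        lines.append(
            "Little's test is degenerate (a single missingness pattern, df=0); "
            "no evidence about the mechanism is available from it."
        )
    elif little.p_value >= alpha:
        verdict = "MCAR-not-rejected"
        lines.append(
            f"Little's test does not reject MCAR (d2={little.d2:.1f}, "
            f"df={little.df}, p={little.p_value:.3f} >= {alpha})."
        )
    else:
        lines.append(
            f"Little's test rejects MCAR (d2={little.d2:.1f}, df={little.df}, "
            f"p={little.p_value:.3g} < {alpha})."
        )
        rf_signal = rf.oob_auc > auc_band
        lines.append(
            f"Random forest out-of-bag AUC {rf.oob_auc:.3f} is "
            f"{'above' if rf_signal else 'within'} the no-signal band "
            f"(edge {auc_band})."
        )
        if sig_terms:
            lines.append(
                "GEE finds significant missingness predictors: "
                + ", ".join(sig_terms) + "."
            )
        else:
            lines.append("GEE finds no significant missingness predictor.")
        if rf_signal or sig_terms:
            verdict = "consistent-with-MAR"
            lines.append(
                "Missingness is predictable from observed variables: the data "
                "are consistent with MAR (MNAR can never be ruled out by "
                "observed-variable models)."
            )
        else:
            verdict = "inconclusive"
            lines.append(
                "MCAR is rejected but neither classifier finds an "
                "observed-variable signal: inconclusive."
            )
    return MechanismDiagnosis(
        little_p=float(little.p_value),
        rf_oob_auc=float(rf.oob_auc),
        gee_significant_terms=sig_terms,
        verdict=verdict,
        narrative=" ".join(lines),
        alpha=alpha,
        auc_band=auc_band,
    )


@dataclass
class ReportBundle:
    """Everything the end-to-end pipeline produced."""

    dataset: LongitudinalDataset
    rates_overall: object
    rates_by_night: object
    pattern_table: object
    little: LittleResult | None
    rf: RFFit | None
    gee: GEEFit | None
    agreement: AgreementTable | None
    diagnosis: MechanismDiagnosis | None
    config: dict = field(default_factory=dict)


def run_pipeline(
    dataset: LongitudinalDataset | None = None,
    generator_config: GeneratorConfig | None = None,
    csv_path=None,
    alpha: float = 0.05,
    auc_band: float = DEFAULT_AUC_BAND,
    n_trees: int = 500,
    seed: int = 0,
    predictors=None,
    select_structure: bool = False,
    out_dir=None,
) -> ReportBundle:
    """Run patterns -> Little -> RF -> GEE -> agreement -> diagnosis.

    Exactly one data source must be supplied: an in-memory dataset, a
    generator config, or a CSV path.  With zero missing nights the pipeline
    reports the descriptives and exits early (there is no mechanism to
    diagnose).  If ``out_dir`` is given, every table is written there as
    CSV/JSON plus a human-readable ``report.txt``.
    """
    sources = [s is not None for s in (dataset, generator_config, csv_path)]
    if sum(sources) != 1:
        raise ValueError("supply exactly one of dataset, generator_config, csv_path")
    stage = "ingest"
    try:
        if generator_config is not None:
            ds = generate(generator_config)
        elif csv_path is not None:
            ds = read_long_csv(csv_path)
        else:
            ds = dataset

        stage = "patterns"
        rates_all = missingness_rates(ds, by="none")
        rates_night = missingness_rates(ds, by="night_index")
        pt = enumerate_patterns(ds)

        bundle = ReportBundle(
            dataset=ds,
            rates_overall=rates_all,
            rates_by_night=rates_night,
            pattern_table=pt,
            little=None, rf=None, gee=None, agreement=None, diagnosis=None,
            config={"alpha": alpha, "auc_band": auc_band, "n_trees": n_trees,
                    "seed": seed},
        )
        if ds.n_missing_nights == 0:
            logger.info("zero missing nights; nothing to diagnose")
            _write_bundle(bundle, out_dir)
            return bundle

        stage = "little"
        bundle.little = little_test(to_wide(ds))

        stage = "random-forest"
        bundle.rf = fit_rf(ds, n_trees=n_trees, seed=seed, predictors=predictors)

        stage = "gee"
        terms = DEFAULT_PREDICTORS if predictors is None else list(predictors)
        corstr = "exchangeable"
        if select_structure:
            corstr, _ = select_corstr(ds, terms=terms)
        bundle.gee = forward_select(ds, candidate_terms=terms, alpha=alpha,
                                    corstr=corstr)

        stage = "agreement"
        bundle.agreement = compare_predictions(
            bundle.rf.predictions["predicted"],
            bundle.gee.predictions["predicted"],
            keys=(
                bundle.rf.predictions[["participant_id", "night_index"]]
                .itertuples(index=False),
                bundle.gee.predictions[["participant_id", "night_index"]]
                .itertuples(index=False),
            ),
        )

        stage = "diagnosis"
        bundle.diagnosis = diagnose(
            bundle.little, bundle.rf, bundle.gee, alpha=alpha, auc_band=auc_band
        )
        _write_bundle(bundle, out_dir)
        return bundle
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _write_bundle(bundle: ReportBundle, out_dir) -> None:
    if out_dir is None:
        return
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_long_csv(bundle.dataset, out / "data_long.csv")
    bundle.rates_overall.table.to_csv(out / "rates_overall.csv", index=False)
    bundle.rates_by_night.table.to_csv(out / "rates_by_night.csv", index=False)
    bundle.pattern_table.to_frame().to_csv(out / "patterns.csv", index=False)
    report = [
        f"participants: {bundle.dataset.n_participants}",
        f"nights: {bundle.dataset.n_total_nights}",
        f"missing nights: {bundle.dataset.n_missing_nights} "
        f"({bundle.rates_overall.overall['percent']}%)",
        f"distinct missingness patterns: {bundle.pattern_table.n_patterns}",
    ]
    if bundle.little is not None:
        json.dump(
            asdict(bundle.little), (out / "little.json").open("w"),
            indent=2, default=str,
        )
        report.append(str(bundle.little))
    if bundle.rf is not None:
        rf = bundle.rf
        json.dump(
            {
                "auc": rf.auc,
                "oob_auc": rf.oob_auc,
                "confusion": asdict(rf.confusion),
                "oob_confusion": asdict(rf.oob_confusion),
                "metrics": rf.metrics,
                "importances": rf.variable_importances.to_dict(),
                "n_trees": rf.n_trees,
            },
            (out / "rf.json").open("w"), indent=2, default=str,
        )
        rf.predictions.to_csv(out / "rf_predictions.csv", index=False)
        report.append(f"random forest: AUC={rf.auc:.3f}, OOB AUC={rf.oob_auc:.3f}")
    if bundle.gee is not None:
        gee = bundle.gee
        json.dump(
            {
                "coefficients": gee.coefficients.to_dict(orient="index"),
                "alpha": gee.alpha,
                "qic": gee.qic,
                "confusion": asdict(gee.confusion),
                "metrics": gee.metrics,
                "selected_terms": gee.selected_terms,
                "step_trace": gee.step_trace,
            },
            (out / "gee.json").open("w"), indent=2, default=str,
        )
        gee.predictions.to_csv(out / "gee_predictions.csv", index=False)
        report.append(
            f"GEE: selected terms {gee.selected_terms}, QIC={gee.qic:.1f}"
        )
    if bundle.agreement is not None:
        json.dump(asdict(bundle.agreement), (out / "agreement.json").open("w"),
                  indent=2)
        report.append(
            f"model agreement: {bundle.agreement.n_agree}/"
            f"{bundle.agreement.total} ({bundle.agreement.agreement_percent}%)"
        )
    if bundle.diagnosis is not None:
        json.dump(asdict(bundle.diagnosis), (out / "diagnosis.json").open("w"),
                  indent=2)
        report.append(f"verdict: {bundle.diagnosis.verdict}")
        report.append(bundle.diagnosis.narrative)
    (out / "report.txt").write_text("\n".join(report) + "\n")
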