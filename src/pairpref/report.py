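"""End-to-end analysis pipeline and report rendering.

``run_analysis`` chains validation → maximum-likelihood fit → pairwise
significance matrix → quasi-variances → global likelihood-ratio test and
collects everything in an :class:`AnalysisReport`.  Rendered (Markdown)
tables round to 2 decimals; the JSON export keeps full precision, so every
printed number is reproducible from the machine output by rounding only.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import IO

import numpy as np
import pandas as pd

from . import __version__
from .btmodel import BTFit, LRTResult, PairwiseTable, fit, lrt_vs_null, pairwise_table
from .data_model import CountMatrices, DataError, validate
from .quasivar import QuasiVariances, quasi_variances

__all__ = ["AnalysisReport", "AnalysisError", "run_analysis"]


class AnalysisError(RuntimeError):
    """Pipeline failure, naming the stage that raised."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"analysis failed at stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class AnalysisReport:
    """Complete result bundle for one paired-comparison analysis."""

    fit: BTFit
    pairwise: PairwiseTable
    quasi: QuasiVariances
    global_test: LRTResult
    win_loss_tallies: dict[str, dict[str, int]]
    provenance: dict

    @property
    def items(self):
        return self.fit.items

    def coefficient_table(self) -> pd.DataFrame:
        """Per-item β, SE, two-sided Wald p and quasi-SE (reference first
        convention: its β is 0 with no SE/p of its own)."""
        rows = []
        for lab in self.items:
            is_ref = lab == self.fit.reference
            rows.append({
                "item": lab,
                "beta": self.fit.beta_dict[lab],
                "se": np.nan if is_ref else self.fit.se(lab),
                "p_value": np.nan if is_ref else self.fit.wald_p(lab),
                "quasi_se": self.quasi.quasi_se[lab],
            })
        return pd.DataFrame(rows).set_index("item")

    def ranking(self) -> list[str]:
        """Items ordered from best- to worst-liked (descending β)."""
        return sorted(self.items, key=lambda x: -self.fit.beta_dict[x])

    def to_dict(self) -> dict:
        return {
            "items": list(self.items),
            "reference": self.fit.reference,
            "beta": self.fit.beta_dict,
            "se": {x: self.fit.se(x) for x in self.items},
            "p_value": {x: self.fit.wald_p(x) for x in self.items
                        if x != self.fit.reference},
            "quasi_variance": self.quasi.q,
            "quasi_se": self.quasi.quasi_se,
            "quasi_worst_relative_error": self.quasi.worst_relative_error,
            "pairwise_p": self.pairwise.to_frame("p_values").to_dict(),
            "pairwise_estimates": self.pairwise.to_frame("estimates").to_dict(),
            "global_test": {
                "statistic": self.global_test.statistic,
                "df": self.global_test.df,
                "p_value": self.global_test.p_value,
                "loglik_full": self.global_test.loglik_full,
                "loglik_null": self.global_test.loglik_null,
            },
            "win_loss_tallies": self.win_loss_tallies,
            "loglik": self.fit.loglik,
            "n_obs": self.fit.n_obs,
            "provenance": self.provenance,
        }

    def to_json(self, dest: str | Path | IO[str] | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, allow_nan=True)
        if dest is not None:
            if hasattr(dest, "write"):
                dest.write(text)
            else:
                Path(dest).write_text(text)
        return text

    def to_markdown(self, dest: str | Path | IO[str] | None = None) -> str:
        coef = self.coefficient_table().round(2)
        pw = self.pairwise.to_frame("p_values").round(2)
        tallies = pd.DataFrame(self.win_loss_tallies).T[["preferred", "not_preferred"]]
        gt = self.global_test
        lines = [
            "# Paired-comparison preference analysis",
            "",
            f"{self.fit.n_obs} judgments over {len(self.items)} items; "
            f"reference category: {self.fit.reference}.",
            "",
            "## Win/loss tallies",
            "",
            tallies.to_string(),
            "",
            "## Worth coefficients",
            "",
            coef.to_string(),
            "",
            "## Pairwise two-sided p-values",
            "",
            pw.to_string(),
            "",
            "## Global test against equal worths",
            "",
            f"LR statistic {gt.statistic:.2f} on {gt.df} df, "
            f"p = {gt.p_value:.2e}.",
            "",
            f"Ranking (best first): {' > '.join(self.ranking())}",
            "",
        ]
        text = "\n".join(lines)
        if dest is not None:
            if hasattr(dest, "write"):
                dest.write(text)
            else:
                Path(dest).write_text(text)
        return text


def run_analysis(counts: CountMatrices, reference: str | None = None) -> AnalysisReport:
    """Run the full pipeline on aggregated counts.

    Deterministic for fixed input; any stage error propagates wrapped in
    :class:`AnalysisError` with the stage name.  The reference defaults to
    the first item (worth has no natural zero, so the choice is arbitrary
    and affects only the parametrization).
    """
    try:
        report = validate(counts)
        if not report.consistent:
            raise DataError(f"inconsistent counts for pairs "
                            f"{[f[:2] for f in report.pair_failures]}")
        if report.total_judgments == 0:
            raise DataError("no judgments to analyze")
    except Exception as e:
        raise AnalysisError("validate", e) from e

    try:
        fit_result = fit(counts, reference=reference)
    except Exception as e:
        raise AnalysisError("fit", e) from e
    try:
        pw = pairwise_table(fit_result)
    except Exception as e:
        raise AnalysisError("pairwise_table", e) from e
    try:
        qv = quasi_variances(fit_result)
    except Exception as e:
        raise AnalysisError("quasi_variances", e) from e
    try:
        gt = lrt_vs_null(counts, reference=reference)
    except Exception as e:
        raise AnalysisError("lrt_vs_null", e) from e

    tallies = {lab: {"preferred": report.win_tallies[lab],
                     "not_preferred": report.loss_tallies[lab]}
               for lab in counts.items}
    digest = hashlib.sha256(
        counts.comparisons.tobytes() + counts.wins.tobytes()).hexdigest()
    provenance = {"input_sha256": digest, "package_version": __version__,
                  "reference": fit_result.reference}
    return AnalysisReport(fit=fit_result, pairwise=pw, quasi=qv,
                          global_test=gt, win_loss_tallies=tallies,
                          provenance=provenance)
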