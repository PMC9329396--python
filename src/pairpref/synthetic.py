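"""Study simulator and parameter-recovery experiments.

Simulates complete forced-choice tasting studies under the Bradley–Terry
model: a randomized design is drawn first (same constraints as the real
study — up to ``max_per_subject`` judgments per subject, no repeated
combination within a subject), then each judgment's outcome is a Bernoulli
draw with success probability expit(β_first − β_second + δ).  One master
seed deterministically spawns independent sub-streams for the design and
for the outcomes, so the two can be varied independently.

The default scenario mirrors the eight-thickener study: 8 items, 37
subjects, up to 7 judgments each (224–259 judgments per replicate).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO

import numpy as np

from . import btmodel, design
from .data_model import ComparisonRecord, DataError, ItemSet, aggregate

__all__ = ["SimulationScenario", "simulate_study", "recovery_experiment",
           "RecoverySummary"]

# Worth coefficients of the magnitude the eight-thickener study estimated,
# used as a realistic default truth for recovery experiments.
STUDY_LIKE_BETA = {
    "A1": 0.0, "A2": -2.20, "A3": -1.35, "A4": 1.49,
    "A5": 1.19, "A6": -1.61, "A7": -1.73, "A8": -2.52,
}


@dataclass(frozen=True)
class SimulationScenario:
    """Ground truth and design parameters for one simulated study."""

    items: ItemSet
    true_beta: dict[str, float]
    true_delta: float = 0.0
    n_subjects: int = 37
    max_per_subject: int = 7
    seed: int = 0

    def __post_init__(self):
        missing = [x for x in self.items if x not in self.true_beta]
        if missing:
            raise DataError(f"true_beta missing items {missing}")

    @classmethod
    def study_like(cls, seed: int = 0, true_delta: float = 0.0,
                   n_subjects: int = 37, max_per_subject: int = 7
                   ) -> "SimulationScenario":
        """The eight-item study layout with realistic worth spread."""
        return cls(items=ItemSet(STUDY_LIKE_BETA), true_beta=dict(STUDY_LIKE_BETA),
                   true_delta=true_delta, n_subjects=n_subjects,
                   max_per_subject=max_per_subject, seed=seed)

    def to_json(self, dest: str | Path | IO[str] | None = None) -> str:
        payload = {
            "items": list(self.items),
            "true_beta": self.true_beta,
            "true_delta": self.true_delta,
            "n_subjects": self.n_subjects,
            "max_per_subject": self.max_per_subject,
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=2)
        if dest is not None:
            if hasattr(dest, "write"):
                dest.write(text)
            else:
                Path(dest).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path | IO[str]) -> "SimulationScenario":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            payload = json.loads(Path(source).read_text())
        return cls(items=ItemSet(payload["items"]),
                   true_beta={k: float(v) for k, v in payload["true_beta"].items()},
                   true_delta=float(payload.get("true_delta", 0.0)),
                   n_subjects=int(payload["n_subjects"]),
                   max_per_subject=int(payload["max_per_subject"]),
                   seed=int(payload.get("seed", 0)))


def _spawn_seeds(seed: int) -> tuple[int, np.random.Generator]:
    """Derive (design seed, outcome generator) from one master seed."""
    ss = np.random.SeedSequence(seed)
    design_ss, outcome_ss = ss.spawn(2)
    design_seed = int(design_ss.generate_state(1)[0] & 0x7FFFFFFF)
    return design_seed, np.random.default_rng(outcome_ss)


def simulate_study(scenario: SimulationScenario) -> list[ComparisonRecord]:
    """Simulate every judgment of one study; reproducible from the seed."""
    design_seed, rng = _spawn_seeds(scenario.seed)
    plan = design.make_design(scenario.items, scenario.n_subjects,
                              scenario.max_per_subject, seed=design_seed)
    beta = scenario.true_beta
    records = []
    for subject, pairs in plan.plans.items():
        for first, second in pairs:
            p_first = btmodel.win_probability(beta[first], beta[second],
                                              scenario.true_delta)
            preferred = first if rng.random() < p_first else second
            records.append(ComparisonRecord(subject, first, second, preferred))
    return records


@dataclass(frozen=True)
class RecoverySummary:
    """Monte-Carlo summary of repeated simulate→fit experiments.

    Bias/RMSE/coverage are per item (coverage of the 95% Wald interval for
    β̂ against the simulation truth, contrasts taken to the fitted
    reference).  Replicates with separation are counted and excluded; a
    small study with a wide worth spread genuinely produces some.
    """

    items: ItemSet
    n_replicates: int
    n_used: int
    n_separated: int
    bias: dict[str, float] = field(default_factory=dict)
    rmse: dict[str, float] = field(default_factory=dict)
    coverage: dict[str, float] = field(default_factory=dict)
    delta_bias: float | None = None
    delta_rmse: float | None = None
    delta_coverage: float | None = None

    @property
    def max_abs_bias(self) -> float:
        return max(abs(v) for v in self.bias.values()) if self.bias else 0.0


def recovery_experiment(
    scenario: SimulationScenario,
    n_replicates: int,
    fit_order_term: bool | None = None,
    z95: float = 1.959963984540054,
) -> RecoverySummary:
    """Repeatedly simulate and refit; summarize estimation quality.

    The order term is included in the fit iff a nonzero δ is under test
    (override with ``fit_order_term``).  Per-replicate seeds are spawned
    deterministically from the scenario seed.
    """
    if fit_order_term is None:
        fit_order_term = scenario.true_delta != 0.0
    items = scenario.items
    reference = items.items[0]
    truth = np.array([scenario.true_beta[x] - scenario.true_beta[reference]
                      for x in items])

    rep_seeds = np.random.SeedSequence(scenario.seed).spawn(max(n_replicates, 1))
    errors, covered, delta_rows = [], [], []
    n_separated = 0
    for r in range(n_replicates):
        rep_seed = int(rep_seeds[r].generate_state(1)[0] & 0x7FFFFFFF)
        rep = SimulationScenario(items=items, true_beta=scenario.true_beta,
                                 true_delta=scenario.true_delta,
                                 n_subjects=scenario.n_subjects,
                                 max_per_subject=scenario.max_per_subject,
                                 seed=rep_seed)
        records = simulate_study(rep)
        try:
            if fit_order_term:
                f = btmodel.fit_with_order(records, reference=reference,
                                           items=items)
            else:
                f = btmodel.fit(aggregate(records, items), reference=reference)
        except (btmodel.SeparationError, btmodel.ConvergenceError):
            n_separated += 1
            continue
        err = f.beta - truth
        ses = np.array([f.se(x) for x in items])
        with np.errstate(invalid="ignore"):
            cov = np.abs(err) <= z95 * ses
        cov[items.index(reference)] = True  # reference pinned, trivially exact
        errors.append(err)
        covered.append(cov)
        if fit_order_term:
            d_err = f.order_coef - scenario.true_delta
            delta_rows.append((d_err, abs(d_err) <= z95 * f.order_se))

    n_used = len(errors)
    if n_used == 0:
        return RecoverySummary(items=items, n_replicates=n_replicates,
                               n_used=0, n_separated=n_separated)
    E = np.vstack(errors)
    Cv = np.vstack(covered)
    free = [x for x in items if x != reference]
    summary = RecoverySummary(
        items=items, n_replicates=n_replicates, n_used=n_used,
        n_separated=n_separated,
        bias={x: float(E[:, items.index(x)].mean()) for x in free},
        rmse={x: float(np.sqrt((E[:, items.index(x)] ** 2).mean())) for x in free},
        coverage={x: float(Cv[:, items.index(x)].mean()) for x in free},
        delta_bias=float(np.mean([d for d, _ in delta_rows])) if delta_rows else None,
        delta_rmse=float(np.sqrt(np.mean([d * d for d, _ in delta_rows])))
        if delta_rows else None,
        delta_coverage=float(np.mean([c for _, c in delta_rows]))
        if delta_rows else None,
    )
    return summary
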