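"""In-silico knockout screen over the five entry groups.

Every combination of the entry groups IRF1, IRF4, IRF8, AP1 and ETS is set
to 0 (knockout) or 100 (expressed) tokens, simulated, and summarised into a
qualitative truth table of the functional outputs.  The default expectation
formulas encode the literature-derived behaviour the network is built to
recapitulate: Th1 needs IRF1 or the IRF8:ETS pair, Th2 needs IRF4:ETS,
Th17 needs IRF4:AP-1, and class I antigen presentation follows Th1.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .engine import Marking, SimulationConfig, simulate, summarize_outputs
from .model import PetriNetModel, validate_model
from .oracle import qualitative_call

ENTRY_GROUP_ORDER = ("IRF1", "IRF4", "IRF8", "AP1", "ETS")

DEFAULT_EXPECTATIONS = {
    "Th1": "IRF1 or (IRF8 and ETS)",
    "Th2": "IRF4 and ETS",
    "Th17": "IRF4 and AP1",
    "antigen_presentation_class_I": "IRF1 or (IRF8 and ETS)",
}


@dataclass(frozen=True)
class EntryCombination:
    """0/100 token flags for the five entry groups; family flags apply to
    every member of the family."""

    flags: tuple[tuple[str, int], ...]

    @classmethod
    def from_values(cls, irf1: int, irf4: int, irf8: int, ap1: int, ets: int):
        vals = (irf1, irf4, irf8, ap1, ets)
        if any(v not in (0, 100) for v in vals):
            raise ValueError("entry flags must be 0 or 100")
        return cls(tuple(zip(ENTRY_GROUP_ORDER, vals)))

    def as_dict(self) -> dict[str, int]:
        return dict(self.flags)

    def to_marking(self, model: PetriNetModel) -> Marking:
        tokens: dict[str, int] = {}
        for group, value in self.flags:
            for p in model.places_in_group(group):
                tokens[p.id] = value
        return Marking(tokens)


@dataclass
class TruthTable:
    """One row per entry combination: flags, per-output summaries and calls."""

    combinations: list[EntryCombination]
    summaries: list[dict[str, float]]
    calls: list[dict[str, str]]

    def __len__(self) -> int:
        return len(self.combinations)

    @property
    def output_ids(self) -> tuple[str, ...]:
        return tuple(self.summaries[0]) if self.summaries else ()

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for combo, summary, calls in zip(
            self.combinations, self.summaries, self.calls
        ):
            row = combo.as_dict()
            for pid in summary:
                row[f"{pid}_summary"] = summary[pid]
                row[f"{pid}_call"] = calls[pid]
            rows.append(row)
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    def row(self, **group_values: int) -> int:
        """Index of the row with the given entry-group values (rest 0)."""
        want = {g: 0 for g in ENTRY_GROUP_ORDER}
        want.update(group_values)
        for i, combo in enumerate(self.combinations):
            if combo.as_dict() == want:
                return i
        raise KeyError(f"no combination {want}")


def enumerate_combinations() -> list[EntryCombination]:
    """All 32 combinations in lexicographic order, IRF1 the slowest bit."""
    combos = []
    for i in range(32):
        bits = [100 if (i >> (4 - j)) & 1 else 0 for j in range(5)]
        combos.append(EntryCombination.from_values(*bits))
    return combos


def run_knockout_scan(model: PetriNetModel,
                      config: SimulationConfig) -> TruthTable:
    """Simulate every 0/100 entry combination and tabulate output activity.

    Rows are independent simulations sharing the configured seed (the random
    streams depend only on the seed, not the marking).
    """
    report = validate_model(model)
    if not report.ok:
        raise ValueError(f"model fails validation: {report.errors}")
    combos = enumerate_combinations()
    summaries, calls = [], []
    for combo in combos:
        marking = combo.to_marking(model)
        trace = simulate(model, marking, config)
        summary = summarize_outputs(trace, config.summary_window)
        qc = qualitative_call(model, marking, summary)
        summaries.append(summary)
        calls.append(qc.calls)
    return TruthTable(combos, summaries, calls)


def _evaluate_formula(formula: str, flags: dict[str, int]) -> bool:
    env = {group: value > 0 for group, value in flags.items()}
    try:
        result = eval(formula, {"__builtins__": {}}, env)  # noqa: S307
    except (SyntaxError, NameError, TypeError) as exc:
        raise ValueError(
            f"malformed expectation formula {formula!r}: {exc}; formulas are "
            f"Boolean expressions over {ENTRY_GROUP_ORDER}"
        ) from exc
    return bool(result)


def check_truth_table(table: TruthTable,
                      expectations: dict[str, str] | None = None) -> list[dict]:
    """Return one violation record per (row, output) where the observed call
    disagrees with the expectation formula; empty list means the screen
    recapitulates every expectation."""
    if len(table) == 0:
        raise ValueError("empty truth table")
    if expectations is None:
        expectations = DEFAULT_EXPECTATIONS
    violations = []
    for i, (combo, calls) in enumerate(zip(table.combinations, table.calls)):
        flags = combo.as_dict()
        for output, formula in expectations.items():
            if output not in calls:
                raise ValueError(f"truth table has no output column {output!r}")
            expected = "active" if _evaluate_formula(formula, flags) else "inactive"
            if calls[output] != expected:
                violations.append({
                    "row": i, "flags": flags, "output": output,
                    "expected": expected, "observed": calls[output],
                })
    return violations
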