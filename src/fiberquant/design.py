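"""Cohort bookkeeping: which samples exist and how they pair within mice.

The in-vivo design injects a scramble-shRNA control virus (Scram) into one
tibialis anterior and the Pabpn1-shRNA virus (shPab) into the contralateral
muscle of the same mouse, so every mouse contributes one matched
Scram/shPab pair; paired statistics must respect that pairing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

SCRAM = "Scram"
SHPAB = "shPab"
PBS = "PBS"


def sample_id(mouse: str, condition: str) -> str:
    return f"{mouse}_{condition}"


@dataclass
class CohortDesign:
    """Samples and contralateral pairs of a paired Scram/shPab cohort.

    Attributes
    ----------
    samples
        DataFrame with columns ``sample``, ``mouse``, ``condition``.
    pairs
        List of ``(scram_sample, shpab_sample)`` tuples, one per mouse that
        carries both conditions.
    """

    samples: pd.DataFrame
    pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        required = {"sample", "mouse", "condition"}
        if not required.issubset(self.samples.columns):
            raise ValueError(f"samples frame needs columns {sorted(required)}")
        if self.samples["sample"].duplicated().any():
            raise ValueError("duplicate sample ids in design")
        mouse_of = dict(zip(self.samples["sample"], self.samples["mouse"]))
        seen: set[str] = set()
        for a, b in self.pairs:
            if mouse_of.get(a) != mouse_of.get(b):
                raise ValueError(f"pair ({a}, {b}) spans two mice")
            if a in seen or b in seen:
                raise ValueError("a sample appears in more than one pair")
            seen.update((a, b))

    @property
    def mice(self) -> list[str]:
        return list(dict.fromkeys(self.samples["mouse"]))

    def samples_for(self, condition: str) -> list[str]:
        sel = self.samples[self.samples["condition"] == condition]
        return list(sel["sample"])

    def mouse_of(self, sample: str) -> str:
        row = self.samples[self.samples["sample"] == sample]
        if row.empty:
            raise KeyError(f"unknown sample {sample!r}")
        return str(row["mouse"].iloc[0])

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        frame = self.samples.copy()
        pair_of = {a: b for a, b in self.pairs}
        frame["paired_with"] = [
            pair_of.get(s, next((a for a, b in self.pairs if b == s), ""))
            for s in frame["sample"]
        ]
        frame.to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortDesign":
        frame = pd.read_csv(path, dtype=str).fillna("")
        pairs = []
        cond = dict(zip(frame["sample"], frame["condition"]))
        for s, p in zip(frame["sample"], frame.get("paired_with", "")):
            if p and cond.get(s) == SCRAM:
                pairs.append((s, p))
        return cls(samples=frame[["sample", "mouse", "condition"]], pairs=pairs)


def generate_cohort(
    n_mice: int, conditions: tuple[str, ...] = (SCRAM, SHPAB)
) -> CohortDesign:
    """Build a paired cohort: one sample per condition per mouse.

    When both Scram and shPab are among ``conditions``, each mouse's two
    contralateral samples form a pair.
    """
    if n_mice < 1:
        raise ValueError("n_mice must be >= 1")
    rows = []
    for i in range(1, n_mice + 1):
        mouse = f"m{i}"
        for cond in conditions:
            rows.append({"sample": sample_id(mouse, cond), "mouse": mouse, "condition": cond})
    samples = pd.DataFrame(rows)
    pairs = []
    if SCRAM in conditions and SHPAB in conditions:
        pairs = [
            (sample_id(f"m{i}", SCRAM), sample_id(f"m{i}", SHPAB))
            for i in range(1, n_mice + 1)
        ]
    return CohortDesign(samples=samples, pairs=pairs)
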