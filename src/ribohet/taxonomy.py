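"""Two-axis maturation-state taxonomy for pre-50S intermediates.

Each conformational class is mapped to a state named ``<digit><letter>``:

* the digit (1-4) is the maturation stage of the peptidyl transferase
  center (PTC), keyed on the folding of the central protuberance (CP) and
  of helices H73, H90-93 and H89:

  1. only the core is folded (CP below the folded threshold);
  2. CP folded, PTC helices not yet (H73 or H90-93 below threshold);
  3. H73 and H90-93 folded, H89 still flexible;
  4. all PTC helices folded — mature PTC.

* the letter (A-D) bins the H68/69 occupancy from undocked (A) to fully
  docked (D).

A category occupancy is the mean occupancy over the blocks mapped to that
category. The folded threshold θ defaults to 0.5 and the H68/69 bin edges
to 0.25/0.5/0.75; both are conventions, configurable per study.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .blocks import BlockLibrary
from .errors import ComparisonError, ConsistencyError, RuleError, ValidationError
from .clustering import ClassAssignment

__all__ = [
    "H68_LETTERS",
    "TaxonomyRules",
    "StateLabel",
    "StateSummary",
    "assign_state",
    "state_fractions",
    "compare_state_distributions",
]

H68_LETTERS = ("A", "B", "C", "D")

# category groups the PTC axis keys on
_PTC_GROUPS = ("CP", "H73", "H90_93", "H89")


@dataclass(frozen=True)
class StateLabel:
    """Maturation state, e.g. '3D': PTC stage 3, H68/69 docked (D)."""

    ptc_stage: int
    h68_stage: str

    def __post_init__(self) -> None:
        if self.ptc_stage not in (1, 2, 3, 4):
            raise ValidationError(f"PTC stage must be 1-4, got {self.ptc_stage}")
        if self.h68_stage not in H68_LETTERS:
            raise ValidationError(f"H68/69 stage must be A-D, got {self.h68_stage!r}")

    def __str__(self) -> str:
        return f"{self.ptc_stage}{self.h68_stage}"

    @classmethod
    def parse(cls, text: str) -> "StateLabel":
        if len(text) != 2:
            raise ValidationError(f"cannot parse state label {text!r}")
        return cls(ptc_stage=int(text[0]), h68_stage=text[1])


@dataclass
class TaxonomyRules:
    """Folded threshold, H68/69 bin edges, and block → category grouping.

    ``groups`` maps each rule category (core, CP, H73, H90_93, H89, H68_69)
    to the block names whose mean occupancy represents it.
    """

    groups: dict[str, list[str]]
    theta: float = 0.5
    h68_bins: tuple[float, float, float] = (0.25, 0.5, 0.75)

    def __post_init__(self) -> None:
        if not 0.0 < self.theta < 1.0:
            raise ValidationError(f"theta must be in (0, 1), got {self.theta}")
        edges = tuple(float(e) for e in self.h68_bins)
        if len(edges) != 3 or not (0.0 < edges[0] < edges[1] < edges[2] < 1.0):
            raise ValidationError(
                f"h68_bins must be 3 strictly increasing edges inside (0, 1), got {edges}"
            )
        self.h68_bins = edges
        for group in (*_PTC_GROUPS, "H68_69"):
            if not self.groups.get(group):
                raise ValidationError(f"taxonomy rules define no blocks for group {group!r}")

    @classmethod
    def from_library(
        cls,
        library: BlockLibrary,
        theta: float = 0.5,
        h68_bins: tuple[float, float, float] = (0.25, 0.5, 0.75),
    ) -> "TaxonomyRules":
        """Derive the grouping from a block library.

        core, CP and H68_69 groups come from category tags; the individual
        PTC helices H73, H89 and H90-93 are matched by block name within the
        PTC category (e.g. blocks named H73, H89, H90, H90_93, H90-93).
        """
        def named(*prefixes: str) -> list[str]:
            return [
                b.name
                for b in library.by_category("PTC")
                if any(b.name.replace("-", "_").startswith(p) for p in prefixes)
            ]

        groups = {
            "core": [b.name for b in library.by_category("core")],
            "CP": [b.name for b in library.by_category("CP")],
            "H68_69": [b.name for b in library.by_category("H68_69")],
            "H73": named("H73"),
            "H89": named("H89"),
            "H90_93": named("H90_93", "H90", "H91", "H92", "H93"),
        }
        return cls(groups=groups, theta=theta, h68_bins=h68_bins)

    def signature(self) -> dict:
        return {
            "theta": self.theta,
            "h68_bins": list(self.h68_bins),
            "groups": {k: sorted(v) for k, v in self.groups.items()},
        }


def _group_occupancy(occupancy: pd.Series, rules: TaxonomyRules, group: str) -> float:
    blocks = rules.groups[group]
    missing = [b for b in blocks if b not in occupancy.index]
    if missing:
        raise RuleError(f"occupancy vector lacks blocks {missing} for group {group!r}")
    return float(occupancy[blocks].mean())


def assign_state(class_occupancy: pd.Series, rules: TaxonomyRules) -> StateLabel:
    """Map a per-block mean occupancy vector to a maturation state.

    The PTC stage climbs CP → H73/H90-93 → H89 against the folded threshold
    θ; the H68/69 letter bins the H68/69 group occupancy. Raising any group
    occupancy can only raise (never lower) either axis.
    """
    occ = {g: _group_occupancy(class_occupancy, rules, g) for g in (*_PTC_GROUPS, "H68_69")}
    theta = rules.theta
    if occ["CP"] < theta:
        stage = 1
    elif occ["H73"] < theta or occ["H90_93"] < theta:
        stage = 2
    elif occ["H89"] < theta:
        stage = 3
    else:
        stage = 4
    letter = H68_LETTERS[int(np.searchsorted(rules.h68_bins, occ["H68_69"], side="right"))]
    return StateLabel(ptc_stage=stage, h68_stage=letter)


@dataclass
class StateSummary:
    """Particle-weighted state distribution of one dataset."""

    fractions: pd.Series  # state name -> fraction, sums to 1
    counts: pd.Series  # state name -> particle count
    dataset: str = ""
    taxonomy_signature: dict | None = None

    def __post_init__(self) -> None:
        if abs(float(self.fractions.sum()) - 1.0) > 1e-9:
            raise ConsistencyError(
                f"state fractions sum to {self.fractions.sum()}, expected 1"
            )
        if ((self.fractions < 0) | (self.fractions > 1)).any():
            raise ConsistencyError("state fractions must lie in [0, 1]")

    def ptc_marginal(self) -> pd.Series:
        """Fraction per PTC stage (1-4), summed over H68/69 letters."""
        stages = self.fractions.groupby(
            [StateLabel.parse(s).ptc_stage for s in self.fractions.index]
        ).sum()
        return stages.reindex([1, 2, 3, 4], fill_value=0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"fraction": self.fractions, "particle_count": self.counts}
        ).rename_axis("state")


def state_fractions(
    classes: ClassAssignment,
    states: dict[int, StateLabel],
    volume_counts: np.ndarray,
    dataset: str = "",
    taxonomy_signature: dict | None = None,
) -> StateSummary:
    """Particle-weighted fraction of each state.

    ``states`` maps class label → StateLabel; every volume inherits its
    class's state and contributes its particle count.
    """
    volume_counts = np.asarray(volume_counts, dtype=float)
    if volume_counts.shape != classes.labels.shape:
        raise ConsistencyError(
            f"{volume_counts.size} counts for {classes.labels.size} volumes"
        )
    missing = set(range(1, classes.n_classes + 1)) - set(states)
    if missing:
        raise ConsistencyError(f"no state assigned for classes {sorted(missing)}")
    totals: dict[str, float] = {}
    for label, count in zip(classes.labels, volume_counts):
        name = str(states[int(label)])
        totals[name] = totals.get(name, 0.0) + count
    counts = pd.Series(totals).sort_index()
    fractions = counts / counts.sum()
    return StateSummary(
        fractions=fractions,
        counts=counts,
        dataset=dataset,
        taxonomy_signature=taxonomy_signature,
    )


def compare_state_distributions(a: StateSummary, b: StateSummary) -> pd.DataFrame:
    """Per-state fraction difference b − a; absent states count as 0.

    Raises if the two summaries were produced under different taxonomies
    (checked via their recorded signatures when both carry one).
    """
    if (
        a.taxonomy_signature is not None
        and b.taxonomy_signature is not None
        and a.taxonomy_signature != b.taxonomy_signature
    ):
        raise ComparisonError("summaries use different taxonomies")
    states = sorted(set(a.fractions.index) | set(b.fractions.index))
    fa = a.fractions.reindex(states, fill_value=0.0)
    fb = b.fractions.reindex(states, fill_value=0.0)
    ca = a.counts.reindex(states, fill_value=0).astype(int)
    cb = b.counts.reindex(states, fill_value=0).astype(int)
    return pd.DataFrame(
        {
            f"fraction_{a.dataset or 'a'}": fa,
            f"fraction_{b.dataset or 'b'}": fb,
            f"count_{a.dataset or 'a'}": ca,
            f"count_{b.dataset or 'b'}": cb,
            "delta": fb - fa,
        }
    ).rename_axis("state")
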