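"""Synthetic categorical cohorts and toy claims tables.

The study cohort this package targets — 1022 newly diagnosed young
lung-cancer patients with sixteen categorical risk-factor/outcome
variables — is drawn from a national insurance claims database that
cannot be redistributed.  This module generates stand-in cohorts with
the same marginal level frequencies, optionally with *planted blocks*
of associated category levels (e.g. anxiety co-occurring with
osteoporosis), so that every downstream stage of the pipeline can be
exercised and validated without any data download.

Block dependence is induced by a shared latent Bernoulli variable per
block: with probability equal to the block's *strength* a member
variable copies the latent state (on = the block level, off = a draw
from the remaining levels), otherwise it is drawn independently from
its marginal distribution.  Strength 0 therefore gives exact mutual
independence, strength 1 gives deterministic co-occurrence of all
block levels, and the pairwise odds ratio between members increases
monotonically in between.  Marginals of block members are preserved
only approximately for strength > 0 (the members' level frequencies
are pulled toward the rarest member's frequency); variables outside
any block are allocated exact level counts by largest-remainder
rounding, so their column totals are reproducible integers.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VariableSpec",
    "Block",
    "CohortSpec",
    "generate_cohort",
    "generate_claims",
    "generate_birthdates",
    "generate_blobs",
    "cohort_preset",
    "list_cohort_presets",
    "list_claims_scenarios",
    "TABLE1_LEVEL_COUNTS",
    "TABLE1_N",
    "write_cohort_csv",
    "write_claims_csv",
]

# Study window of the source cohort (first lung-cancer diagnoses
# between 2001-01-01 and 2007-12-31).
STUDY_WINDOW = (datetime.date(2001, 1, 1), datetime.date(2007, 12, 31))


@dataclass(frozen=True)
class VariableSpec:
    """One categorical variable: ordered levels and their marginal probabilities."""

    name: str
    levels: tuple[str, ...]
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise ValueError(f"variable {self.name!r} needs at least 2 levels")
        if len(self.levels) != len(self.probs):
            raise ValueError(f"variable {self.name!r}: levels/probs length mismatch")
        if len(set(self.levels)) != len(self.levels):
            raise ValueError(f"variable {self.name!r} has duplicate levels")
        if any(p < 0 for p in self.probs):
            raise ValueError(f"variable {self.name!r} has negative probabilities")
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ValueError(
                f"variable {self.name!r}: marginal probabilities sum to "
                f"{sum(self.probs)!r}, not 1"
            )


@dataclass(frozen=True)
class Block:
    """A set of (variable, level) members tied together with a given strength."""

    members: tuple[tuple[str, str], ...]
    strength: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError(f"block strength {self.strength} not in [0, 1]")
        if len(self.members) < 2:
            raise ValueError("a block needs at least 2 members")


@dataclass(frozen=True)
class CohortSpec:
    """Full recipe for one synthetic cohort."""

    n_patients: int
    variables: tuple[VariableSpec, ...]
    blocks: tuple[Block, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names")
        by_name = {v.name: v for v in self.variables}
        seen_vars: set[str] = set()
        for b, block in enumerate(self.blocks):
            block_vars = [m[0] for m in block.members]
            if len(set(block_vars)) != len(block_vars):
                raise ValueError(
                    f"infeasible block #{b} {block.members}: two members share a "
                    "variable, so they can never co-occur"
                )
            for var, level in block.members:
                if var not in by_name:
                    raise ValueError(f"block #{b}: unknown variable {var!r}")
                if level not in by_name[var].levels:
                    raise ValueError(f"block #{b}: {var!r} has no level {level!r}")
                if var in seen_vars:
                    raise ValueError(
                        f"infeasible block #{b}: variable {var!r} appears in more "
                        "than one block"
                    )
                seen_vars.add(var)

    def variable(self, name: str) -> VariableSpec:
        return next(v for v in self.variables if v.name == name)


def _exact_counts(probs: np.ndarray, n: int) -> np.ndarray:
    """Integer level counts summing to n, by largest-remainder rounding."""
    target = probs * n
    base = np.floor(target).astype(int)
    short = n - base.sum()
    order = np.argsort(-(target - base), kind="stable")
    base[order[:short]] += 1
    return base


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a patients x variables table of category labels.

    Variables outside any block receive exact level counts (a seeded
    permutation of a fixed multiset); block members are sampled row-wise
    through the shared-latent mechanism described in the module docstring.
    Output is reproducible byte-for-byte given the spec (incl. its seed).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients

    membership: dict[str, tuple[int, str]] = {}
    for b, block in enumerate(spec.blocks):
        for var, level in block.members:
            membership[var] = (b, level)

    # One latent on/off state per block; its rate is the rarest member's
    # marginal so that forcing members on never exceeds their marginal.
    latents = []
    for block in spec.blocks:
        q = min(
            spec.variable(var).probs[spec.variable(var).levels.index(level)]
            for var, level in block.members
        )
        latents.append(rng.random(n) < q)

    columns: dict[str, pd.Categorical] = {}
    for var in spec.variables:
        probs = np.asarray(var.probs, dtype=float)
        if var.name not in membership:
            counts = _exact_counts(probs, n)
            codes = rng.permutation(np.repeat(np.arange(len(var.levels)), counts))
        else:
            b, level = membership[var.name]
            strength = spec.blocks[b].strength
            li = var.levels.index(level)
            base = rng.choice(len(var.levels), size=n, p=probs)
            forced = rng.random(n) < strength
            off_probs = probs.copy()
            off_probs[li] = 0.0
            if off_probs.sum() <= 0:
                raise ValueError(
                    f"infeasible block #{b}: {var.name!r} has no probability "
                    f"mass outside level {level!r}"
                )
            off_probs /= off_probs.sum()
            off_draw = rng.choice(len(var.levels), size=n, p=off_probs)
            codes = np.where(forced, np.where(latents[b], li, off_draw), base)
        columns[var.name] = pd.Categorical.from_codes(
            codes, categories=list(var.levels)
        )
    df = pd.DataFrame(columns)
    df.index = pd.Index([f"P{i:05d}" for i in range(n)], name="patient_id")
    return df


# ---------------------------------------------------------------------------
# Presets mirroring the published cohort's marginal frequencies (n = 1022)
# ---------------------------------------------------------------------------

TABLE1_N = 1022

#: Level counts of the published 1022-patient cohort, variable by variable.
TABLE1_LEVEL_COUNTS: dict[str, dict[str, int]] = {
    "sex": {"Female": 502, "Male": 520},
    "age_group": {"20-29": 154, "30-39": 868},
    "cci": {"0": 870, "1": 91, ">=2": 61},
    "dm": {"Yes": 23, "No": 999},
    "hypertension": {"Yes": 23, "No": 999},
    "asthma": {"Yes": 16, "No": 1006},
    "liver_cirrhosis": {"Yes": 9, "No": 1013},
    "copd": {"Yes": 51, "No": 971},
    "autoimmune": {"Yes": 8, "No": 1014},
    "cerebral": {"Yes": 11, "No": 1011},
    "heart_failure": {"Yes": 2, "No": 1020},
    "hbv": {"Yes": 34, "No": 988},
    "renal": {"Yes": 6, "No": 1016},
    "osteoporosis": {"Yes": 16, "No": 1006},
    "depression": {"Yes": 25, "No": 997},
    "anxiety": {"Yes": 15, "No": 1007},
}

# Planted-association blocks used by the "table1_planted" preset.  All
# member levels have prevalence >= 2% so that, at high strength, each
# block forms a recoverable tight pair of category points.
_PLANTED_BLOCK_MEMBERS: tuple[tuple[tuple[str, str], ...], ...] = (
    (("depression", "Yes"), ("dm", "Yes")),
    (("hbv", "Yes"), ("copd", "Yes")),
    (("hypertension", "Yes"), ("cci", ">=2")),
)


def _table1_variables() -> tuple[VariableSpec, ...]:
    out = []
    for name, counts in TABLE1_LEVEL_COUNTS.items():
        levels = tuple(counts)
        total = sum(counts.values())
        probs = tuple(c / total for c in counts.values())
        out.append(VariableSpec(name, levels, probs))
    return tuple(out)


def cohort_preset(
    name: str,
    n_patients: int = TABLE1_N,
    seed: int = 0,
    strength: float = 0.95,
) -> CohortSpec:
    """Return a named :class:`CohortSpec` preset.

    Presets
    -------
    ``table1``
        Sixteen variables with the published cohort's marginal
        frequencies, no planted association.
    ``table1_planted``
        Same marginals plus three planted two-member blocks
        (depression/DM, HBV/COPD, hypertension/CCI>=2) at the given
        strength; used for category-cluster recovery experiments.
    ``table1_anxiety_osteoporosis``
        Same marginals plus a single anxiety-osteoporosis block at the
        given strength (strength 1 makes the two "Yes" levels co-occur
        deterministically, the qualitative pattern the clustering arm
        should reproduce).
    """
    variables = _table1_variables()
    if name == "table1":
        blocks: tuple[Block, ...] = ()
    elif name == "table1_planted":
        blocks = tuple(Block(m, strength) for m in _PLANTED_BLOCK_MEMBERS)
    elif name == "table1_anxiety_osteoporosis":
        blocks = (Block((("anxiety", "Yes"), ("osteoporosis", "Yes")), strength),)
    else:
        raise ValueError(
            f"unknown cohort preset {name!r}; available: {list_cohort_presets()}"
        )
    return CohortSpec(n_patients=n_patients, variables=variables, blocks=blocks, seed=seed)


def list_cohort_presets() -> list[str]:
    return ["table1", "table1_planted", "table1_anxiety_osteoporosis"]


def planted_block_members(spec: CohortSpec) -> list[list[tuple[str, str]]]:
    """The planted partition of category levels: one group per block."""
    return [list(b.members) for b in spec.blocks]


# ---------------------------------------------------------------------------
# Toy claims tables for the cohort-construction stage
# ---------------------------------------------------------------------------

CLAIMS_COLUMNS = ["patient_id", "visit_date", "icd9", "setting"]


def _scenario_lung_cancer_followup(spec: CohortSpec):
    """Index lung-cancer visit per patient plus confirmation visits.

    Patients whose generated cohort row carries depression (anxiety)
    "Yes" receive three distinct-date confirmation visits coded 311
    (300.00) after their index visit; everyone else gets at most two
    such visits, so the claims stream round-trips through the cohort
    filter to the generated outcome columns.  Index visits start in
    2002 so that confirmation visits never intersect the 2001 baseline
    psychiatric-exclusion window.
    """
    cohort = generate_cohort(spec)
    first_index = STUDY_WINDOW[0] + datetime.timedelta(days=366)
    window_days = (STUDY_WINDOW[1] - first_index).days - 200
    rows = []
    birthdates = {}
    for i, (pid, row) in enumerate(cohort.iterrows()):
        index_date = first_index + datetime.timedelta(days=(i * 37) % window_days)
        age = 25 + i % 15  # 25..39 at index
        birthdates[pid] = index_date.replace(year=index_date.year - age)
        rows.append((pid, index_date, "162.3", "outpatient"))
        if "depression" in cohort.columns and row["depression"] == "Yes":
            for d in (30, 60, 90):
                rows.append((pid, index_date + datetime.timedelta(days=d), "311", "outpatient"))
        elif i % 3 == 0:  # a couple of non-qualifying depression visits
            for d in (30, 60):
                rows.append((pid, index_date + datetime.timedelta(days=d), "311", "outpatient"))
        if "anxiety" in cohort.columns and row["anxiety"] == "Yes":
            for d in (45, 75, 105):
                rows.append((pid, index_date + datetime.timedelta(days=d), "300.00", "outpatient"))
    claims = pd.DataFrame(rows, columns=CLAIMS_COLUMNS)
    return claims, birthdates


def _scenario_toy_filter(spec: CohortSpec):
    """Five hand-built patients exercising every filter rule.

    A and B: eligible, three distinct-date depression visits after the
    index visit (cases).  C: eligible, only two such visits (non-case).
    D: baseline bipolar code (296.4) in 2001, excluded.  E: born 1950,
    over the 20-39 age range at index, excluded.
    """
    d = datetime.date
    rows = [
        ("A", d(2003, 6, 1), "162.3", "outpatient"),
        ("A", d(2003, 7, 1), "311", "outpatient"),
        ("A", d(2003, 8, 1), "311", "outpatient"),
        ("A", d(2003, 9, 1), "300.4", "outpatient"),
        ("B", d(2004, 1, 15), "162.9", "inpatient"),
        ("B", d(2004, 2, 15), "296.25", "outpatient"),
        ("B", d(2004, 3, 15), "296.30", "outpatient"),
        ("B", d(2004, 4, 15), "311", "outpatient"),
        ("C", d(2003, 6, 1), "162.3", "outpatient"),
        ("C", d(2003, 7, 1), "311", "outpatient"),
        ("C", d(2003, 8, 1), "311", "outpatient"),
        ("D", d(2001, 5, 10), "296.4", "outpatient"),
        ("D", d(2003, 6, 1), "162.3", "outpatient"),
        ("E", d(2003, 6, 1), "162.3", "outpatient"),
    ]
    birthdates = {
        "A": d(1975, 3, 1),
        "B": d(1976, 8, 20),
        "C": d(1978, 1, 5),
        "D": d(1977, 6, 30),
        "E": d(1950, 2, 2),
    }
    return pd.DataFrame(rows, columns=CLAIMS_COLUMNS), birthdates


def _scenario_empty(spec: CohortSpec):
    return pd.DataFrame(columns=CLAIMS_COLUMNS), {}


_CLAIMS_SCENARIOS = {
    "lung_cancer_followup": _scenario_lung_cancer_followup,
    "toy_filter": _scenario_toy_filter,
    "empty": _scenario_empty,
}


def list_claims_scenarios() -> list[str]:
    return sorted(_CLAIMS_SCENARIOS)


def _run_scenario(spec: CohortSpec, scenario: str):
    try:
        builder = _CLAIMS_SCENARIOS[scenario]
    except KeyError:
        raise ValueError(
            f"unknown claims scenario {scenario!r}; available: {list_claims_scenarios()}"
        ) from None
    return builder(spec)


def generate_claims(spec: CohortSpec, scenario: str) -> pd.DataFrame:
    """Long-format claims rows (patient_id, visit_date, icd9, setting)."""
    return _run_scenario(spec, scenario)[0]


def generate_birthdates(spec: CohortSpec, scenario: str) -> dict[str, datetime.date]:
    """Birthdates matching :func:`generate_claims` for the same scenario."""
    return _run_scenario(spec, scenario)[1]


# ---------------------------------------------------------------------------
# Planted Gaussian blobs for the cluster-count selection experiments
# ---------------------------------------------------------------------------


def generate_blobs(
    n_points: int,
    k: int,
    separation: float = 6.0,
    spread: float = 0.02,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """k well-separated planar Gaussian blobs; returns (points, true labels).

    Centers sit on a circle whose radius is chosen so the minimum
    center-to-center distance equals ``separation``; each point is its
    center plus isotropic N(0, spread^2) noise.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    if k == 1:
        centers = np.zeros((1, 2))
    else:
        radius = separation / (2.0 * np.sin(np.pi / k))
        angles = 2.0 * np.pi * np.arange(k) / k
        centers = radius * np.column_stack([np.cos(angles), np.sin(angles)])
    labels = np.arange(n_points) % k
    points = centers[labels] + rng.normal(scale=spread, size=(n_points, 2))
    return points, labels


# ---------------------------------------------------------------------------
# CSV writers
# ---------------------------------------------------------------------------


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=True)


def write_claims_csv(claims: pd.DataFrame, path) -> None:
    claims.to_csv(path, index=False)
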