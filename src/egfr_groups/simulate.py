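"""Synthetic screens, cohorts and mutation corpora.

The generators emulate the statistical structure the analyses assume:
7-concentration triplicate dose-response curves with lognormal IC50
noise, mutation x drug selectivity matrices built from group x
drug-class templates, and right-censored survival cohorts with group x
TKI-generation median event times.  Everything is deterministic given a
seed, and every generator also returns its ground truth so each
analysis stage can be tested for parameter recovery.

The default selectivity template encodes the qualitative
structure-function ordering: classical/classical-like most selective
for third-generation TKIs; PACC most selective for second-generation
(covalent) TKIs; Ex20ins-L selective only for Ex20ins-active agents and
select second-generation TKIs; T790M-like-3S selective for
third-generation TKIs; T790M-like-3R retaining selectivity only for
ALK/PKC inhibitors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .classify import Group
from .variants import parse_allele

__all__ = [
    "DEFAULT_DRUG_PANEL",
    "DRUG_CLASSES",
    "MUTATION_POOLS",
    "ScreenTemplate",
    "default_screen_template",
    "generate_mutation_panel",
    "ScreenData",
    "generate_screen",
    "CohortTemplate",
    "generate_cohort",
    "generate_response_cohort",
]

DRUG_CLASSES = ("1st-gen", "2nd-gen", "3rd-gen", "Ex20ins-active", "ALKi", "PKCi")

#: 18-drug panel spanning the six classes (3/4/3/4/2/2), mirroring the
#: breadth of a TKI repurposing screen.
DEFAULT_DRUG_PANEL: tuple[tuple[str, str], ...] = (
    ("erlotinib", "1st-gen"),
    ("gefitinib", "1st-gen"),
    ("icotinib", "1st-gen"),
    ("afatinib", "2nd-gen"),
    ("dacomitinib", "2nd-gen"),
    ("poziotinib", "2nd-gen"),
    ("neratinib", "2nd-gen"),
    ("osimertinib", "3rd-gen"),
    ("rociletinib", "3rd-gen"),
    ("nazartinib", "3rd-gen"),
    ("mobocertinib", "Ex20ins-active"),
    ("tarloxotinib", "Ex20ins-active"),
    ("zipalertinib", "Ex20ins-active"),
    ("sunvozertinib", "Ex20ins-active"),
    ("brigatinib", "ALKi"),
    ("ceritinib", "ALKi"),
    ("midostaurin", "PKCi"),
    ("lestaurtinib", "PKCi"),
)

#: Expected log10(mutant/WT IC50) per (structure group, drug class).
#: Negative = selective/sensitive relative to wild type.
_DEFAULT_EFFECTS: dict[str, dict[str, float]] = {
    Group.CLASSICAL: {
        "1st-gen": -1.5, "2nd-gen": -1.8, "3rd-gen": -2.2,
        "Ex20ins-active": -1.0, "ALKi": 0.0, "PKCi": 0.0,
    },
    Group.CLASSICAL_LIKE: {
        "1st-gen": -1.2, "2nd-gen": -1.5, "3rd-gen": -2.0,
        "Ex20ins-active": -0.9, "ALKi": 0.1, "PKCi": 0.1,
    },
    "T790M-like-3S": {
        "1st-gen": 1.0, "2nd-gen": 0.8, "3rd-gen": -1.5,
        "Ex20ins-active": -0.5, "ALKi": -0.3, "PKCi": -0.3,
    },
    "T790M-like-3R": {
        "1st-gen": 1.2, "2nd-gen": 1.0, "3rd-gen": 0.8,
        "Ex20ins-active": 0.5, "ALKi": -0.8, "PKCi": -0.8,
    },
    Group.EX20INS_L: {
        "1st-gen": 0.5, "2nd-gen": -0.5, "3rd-gen": 0.3,
        "Ex20ins-active": -1.5, "ALKi": 0.3, "PKCi": 0.3,
    },
    Group.PACC: {
        "1st-gen": -0.5, "2nd-gen": -2.0, "3rd-gen": -0.5,
        "Ex20ins-active": -0.8, "ALKi": 0.1, "PKCi": 0.1,
    },
}

#: Curated mutation-name pools per intended structure-function group.
#: Every name parses and the classifier recovers the intended label
#: (asserted by the test suite).
MUTATION_POOLS: dict[str, tuple[str, ...]] = {
    Group.CLASSICAL: (
        "L858R", "E746_A750del", "L747_P753delinsS", "L747_T751del",
        "L747_A755del", "E746_S752delinsV",
    ),
    Group.CLASSICAL_LIKE: (
        "L861Q", "L861R", "A763insFQEA", "A750P", "K754E", "S784F",
        "V834L", "P848L",
    ),
    "T790M-like-3S": (
        "G719A+T790M", "S768I+T790M", "L861Q+T790M", "E709A+T790M",
        "L747_K754delinsATSPE", "G724S+T790M",
    ),
    "T790M-like-3R": (
        "L858R+T790M+C797S", "E746_A750del+T790M+C797S", "L858R+T790M+L718Q",
        "L858R+T790M+L792H", "G719A+T790M+C797S", "E746_A750del+T790M+L718V",
    ),
    Group.EX20INS_L: (
        "A767insASV", "V769insASV", "D770insSVD", "D770insNPG",
        "N771insG", "P772insPR", "H773insNPH", "V774insHV",
    ),
    Group.PACC: (
        "G719A", "G719S", "L718Q", "S768I", "T854I", "L747P", "E709K",
        "G724S", "L792H", "V765L", "G796S", "E709K/G719S",
    ),
}


@dataclass(frozen=True)
class ScreenTemplate:
    """Ground-truth selectivity model for synthetic screens.

    ``effects`` maps (group, drug class) to the expected log10 mutant/WT
    ratio; ``sigma`` is the per-replicate lognormal IC50 noise (log10
    units), ``sigma_mutation`` a per-mutation offset shared across drugs
    and replicates, ``well_sigma`` multiplicative per-well signal noise.
    """

    effects: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: _DEFAULT_EFFECTS
    )
    drugs: tuple[tuple[str, str], ...] = DEFAULT_DRUG_PANEL
    sigma: float = 0.2
    sigma_mutation: float = 0.1
    well_sigma: float = 0.02
    n_replicates: int = 3
    wt_ic50_nm: float = 100.0

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.sigma_mutation < 0 or self.well_sigma < 0:
            raise ValueError("noise scales must be non-negative")

    def effect(self, group: str, drug_class: str) -> float:
        return float(self.effects[group][drug_class])

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.effects).T

    def validate_ordering(self) -> None:
        """Assert the template's qualitative selectivity ordering."""
        f = self.frame()

        def argmin(group):
            return f.loc[group].idxmin()

        checks = {
            Group.CLASSICAL_LIKE: "3rd-gen",
            Group.PACC: "2nd-gen",
            Group.EX20INS_L: "Ex20ins-active",
            "T790M-like-3S": "3rd-gen",
        }
        for group, expected in checks.items():
            if group in f.index and argmin(group) != expected:
                raise ValueError(f"{group} should be most selective for {expected}")
        if "T790M-like-3R" in f.index:
            row = f.loc["T790M-like-3R"]
            neg = set(row.index[row < 0])
            if not neg <= {"ALKi", "PKCi"} or not neg:
                raise ValueError("T790M-like-3R should be selective only for ALKi/PKCi")

    def replace(self, **kwargs) -> "ScreenTemplate":
        return replace(self, **kwargs)


def default_screen_template(**overrides) -> ScreenTemplate:
    tpl = ScreenTemplate(**overrides)
    tpl.validate_ordering()
    return tpl


def generate_mutation_panel(
    counts: Mapping[str, int], seed: int = 0
) -> list[tuple[str, str]]:
    """Sample (mutation string, intended group) pairs from the curated pools
    without replacement."""
    rng = np.random.default_rng(seed)
    panel: list[tuple[str, str]] = []
    for group, count in counts.items():
        if count < 0:
            raise ValueError("counts must be >= 0")
        if count == 0:
            continue
        pool = MUTATION_POOLS[group]
        if count > len(pool):
            raise ValueError(f"only {len(pool)} curated names available for {group}")
        picks = rng.choice(len(pool), size=count, replace=False)
        panel.extend((pool[i], group) for i in sorted(picks))
    for name, _ in panel:
        parse_allele(name)  # every generated string must parse
    return panel


@dataclass
class ScreenData:
    """Synthetic screen: raw wells and/or replicate log-ratios plus truth."""

    truth: pd.DataFrame  # mutation x drug expected log10 ratio
    replicate_logratios: pd.DataFrame  # cell_line, drug, drug_class, replicate, log_ratio, censored
    wells: Optional[pd.DataFrame] = None  # long raw-signal table (raw mode)
    groups: Optional[pd.Series] = None  # mutation -> intended group


def _seven_point_doses(center_nm: float) -> np.ndarray:
    # 7 half-log doses centred on the noise-free IC50 so the 50% crossing
    # is always bracketed; a fixed grid with censoring is available via
    # `fixed_doses`.
    return center_nm * 10.0 ** np.linspace(-1.5, 1.5, 7)


def generate_screen(
    panel: Sequence[tuple[str, str]],
    template: ScreenTemplate = None,
    *,
    seed: int = 0,
    raw: bool = False,
    fixed_doses: Optional[Sequence[float]] = None,
    signal_scale: float = 10000.0,
) -> ScreenData:
    """Simulate a drug screen for a mutation panel.

    Each cell's true IC50 is ``WT_IC50 * 10^(effect + mutation offset)``
    with per-replicate lognormal noise.  In ``raw`` mode per-well
    bioluminescence signals are emitted from an exact unit logistic
    (top 1, bottom 0, hill 1) at 7 half-log doses plus DMSO control
    wells; otherwise per-replicate log-ratios are returned directly.
    Identical seed and configuration give byte-identical tables.
    """
    template = template or default_screen_template()
    rng = np.random.default_rng(seed)
    mutations = [name for name, _ in panel]
    groups = pd.Series({name: grp for name, grp in panel})
    drug_names = [d for d, _ in template.drugs]
    classes = pd.Series({d: c for d, c in template.drugs})

    offsets = {
        m: (rng.normal(0.0, template.sigma_mutation) if template.sigma_mutation > 0 else 0.0)
        for m in mutations
    }
    truth = pd.DataFrame(
        {
            d: [template.effect(groups[m], classes[d]) + offsets[m] for m in mutations]
            for d in drug_names
        },
        index=pd.Index(mutations, name="mutation"),
    )

    rep_rows = []
    well_rows = []
    for m in mutations:
        for d in drug_names:
            base = truth.loc[m, d]
            for rep in range(1, template.n_replicates + 1):
                eps = rng.normal(0.0, template.sigma) if template.sigma > 0 else 0.0
                logratio = base + eps
                rep_rows.append(
                    {"cell_line": m, "drug": d, "drug_class": classes[d],
                     "replicate": rep, "log_ratio": logratio, "censored": False}
                )
                if raw:
                    ic50 = template.wt_ic50_nm * 10.0 ** logratio
                    doses = (np.asarray(fixed_doses, dtype=float) if fixed_doses is not None
                             else _seven_point_doses(template.wt_ic50_nm * 10.0 ** base))
                    well_rows.extend(
                        _wells(m, d, classes[d], rep, doses, ic50, signal_scale,
                               template.well_sigma, rng)
                    )
    # wild-type reference line: IC50 at the WT level per drug (no noise,
    # so that the pipeline's WT-mean denominator is exact)
    if raw:
        for d in drug_names:
            doses = (np.asarray(fixed_doses, dtype=float) if fixed_doses is not None
                     else _seven_point_doses(template.wt_ic50_nm))
            for rep in range(1, template.n_replicates + 1):
                well_rows.extend(
                    _wells("WT", d, classes[d], rep, doses, template.wt_ic50_nm,
                           signal_scale, template.well_sigma, rng)
                )

    replicate_logratios = pd.DataFrame(rep_rows)
    wells = pd.DataFrame(well_rows) if raw else None
    return ScreenData(truth=truth, replicate_logratios=replicate_logratios,
                      wells=wells, groups=groups)


def _wells(cell_line, drug, drug_class, rep, doses, ic50, scale, well_sigma, rng):
    rows = []
    for dose in doses:
        viability = 1.0 / (1.0 + dose / ic50)  # unit logistic, hill 1
        noise = math.exp(rng.normal(0.0, well_sigma)) if well_sigma > 0 else 1.0
        rows.append(
            {"cell_line": cell_line, "drug": drug, "drug_class": drug_class,
             "concentration_nM": float(dose), "replicate": rep,
             "signal": scale * viability * noise, "is_dmso": False}
        )
    dmso_noise = math.exp(rng.normal(0.0, well_sigma)) if well_sigma > 0 else 1.0
    rows.append(
        {"cell_line": cell_line, "drug": drug, "drug_class": drug_class,
         "concentration_nM": 0.0, "replicate": rep,
         "signal": scale * dmso_noise, "is_dmso": True}
    )
    return rows


# --------------------------------------------------------------------------
# Survival cohorts


@dataclass(frozen=True)
class CohortTemplate:
    """Arm design for a synthetic survival cohort.

    ``medians`` maps (group, tki_generation) to the true median event
    time in months; event times are exponential (rate ln2/median) with
    independent uniform right-censoring calibrated to ``censoring``.
    """

    medians: Mapping[tuple[str, str], float]
    n_per_arm: int = 50
    censoring: float = 0.2
    endpoint: str = "TTF"

    def __post_init__(self) -> None:
        if not (0.0 <= self.censoring < 1.0):
            raise ValueError("censoring fraction must be in [0, 1)")
        for arm, median in self.medians.items():
            if median <= 0:
                raise ValueError(f"median for arm {arm} must be positive")


def _uniform_censor_bound(rate: float, fraction: float) -> float:
    """Upper bound u of U(0, u) censoring giving P(C < T) = fraction."""
    if fraction <= 0:
        return float("inf")

    def objective(u):
        return (1.0 - np.exp(-rate * u)) / (rate * u) - fraction

    # objective decreases from 1 (u->0) to 0 (u->inf)
    lo, hi = 1e-9, 1.0
    while objective(hi) > 0:
        hi *= 2.0
        if hi > 1e12:
            break
    return float(optimize.brentq(objective, lo, hi))


def generate_cohort(template: CohortTemplate, seed: int = 0) -> pd.DataFrame:
    """Per-patient survival records for every arm of the template."""
    rng = np.random.default_rng(seed)
    rows = []
    pid = 0
    for (group, generation), median in template.medians.items():
        rate = math.log(2.0) / median
        times = rng.exponential(1.0 / rate, size=template.n_per_arm)
        if template.censoring > 0:
            bound = _uniform_censor_bound(rate, template.censoring)
            censor = rng.uniform(0.0, bound, size=template.n_per_arm)
            observed = np.minimum(times, censor)
            events = (times <= censor).astype(int)
        else:
            observed = times
            events = np.ones(template.n_per_arm, dtype=int)
        for t, e in zip(observed, events):
            pid += 1
            rows.append(
                {"patient_id": f"P{pid:05d}", "group": group,
                 "tki_generation": generation, "endpoint": template.endpoint,
                 "time_months": float(max(t, 1e-9)), "event": int(e)}
            )
    return pd.DataFrame(rows)


def generate_response_cohort(
    orr_by_group: Mapping[str, float],
    n_by_group: Mapping[str, int],
    seed: int = 0,
) -> pd.DataFrame:
    """Best-response records with the requested per-group response
    probability (CR/PR vs SD/PD)."""
    rng = np.random.default_rng(seed)
    rows = []
    pid = 0
    for group, orr in orr_by_group.items():
        if not (0.0 <= orr <= 1.0):
            raise ValueError("response rates must be in [0, 1]")
        for _ in range(n_by_group[group]):
            pid += 1
            if rng.uniform() < orr:
                response = "PR" if rng.uniform() < 0.8 else "CR"
            else:
                response = "PD" if rng.uniform() < 0.5 else "SD"
            rows.append({"patient_id": f"R{pid:05d}", "group": group,
                         "best_response": response})
    return pd.DataFrame(rows)
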