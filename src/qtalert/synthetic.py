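"""Synthetic inputs with known ground truth.

Three generators feed the pipeline end-to-end without any external
data:

* **compound cohorts** — molecules assembled from a hand-curated
  carrier-fragment library on inert alkane scaffolds, with per-alert
  Bernoulli planting at configurable prevalences (defaults: the
  reference screen proportions of the alerts with registered carriers,
  cohort sizes 144 positive / 95 negative). Every product is verified
  against the alert dictionary — planted alerts must match, non-planted
  must not — and re-drawn on violation, so realized per-alert counts
  are exact ground truth.
* **drug–event report tables** — case-level records constructed so that
  per-drug 2x2 aggregation reproduces planted contingency cells
  exactly; drugs share one case universe (one drug per case) and a
  common background event rate. A sampling mode draws the event cells
  binomially for confidence-interval coverage studies.
* **class-signal descriptor matrices** — Gaussian features where a
  chosen subset of columns carries a class mean shift at a stated
  effect size, with a Monte-Carlo estimate of the Bayes error of the
  generating model attached as ground truth.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .alerts import AlertDefinition, match_alert
from .chem_io import CompoundCohort, MoleculeRecord, mol_from_smiles
from .descriptors import DescriptorMatrix
from .disproportionality import ContingencyTable

# ---------------------------------------------------------------------------
# compound cohorts

#: carrier fragments: substituent SMILES attached to a backbone sp3 carbon,
#: each bearing exactly the named alert (verified by unit tests against the
#: packaged dictionary). Keys are dictionary alert names.
DEFAULT_CARRIERS: dict[str, str] = {
    "tertiary aliphatic amines": "N(C)C",
    "aryl halide": "c1ccc(Cl)cc1",
    "alkylarylethers": "Oc1ccccc1",
}

#: alert-free scaffolds (plain alkanes) the carriers attach to
DEFAULT_SCAFFOLDS: tuple[str, ...] = ("C", "CC", "CCC", "CCCC")

#: default planting prevalences (p_pos, p_neg) keyed by alert name, taken
#: from the reference screen proportions of the supported alerts
DEFAULT_PREVALENCES: dict[str, tuple[float, float]] = {
    "tertiary aliphatic amines": (76 / 144, 9 / 95),
    "aryl halide": (54 / 144, 13 / 95),
    "alkylarylethers": (49 / 144, 11 / 95),
}


@dataclass
class CohortSpec:
    n_pos: int = 144
    n_neg: int = 95
    prevalences: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES)
    )
    seed: int = 0
    carriers: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CARRIERS))
    scaffolds: tuple[str, ...] = DEFAULT_SCAFFOLDS
    #: correlated mode: planting an alert also plants its subordinate
    #: alerts (e.g. an aryl-halide carrier necessarily carries halogens)
    implies: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("cohort sizes must be >= 1")
        for name, (pp, pn) in self.prevalences.items():
            if not (0 <= pp <= 1 and 0 <= pn <= 1):
                raise ValueError(f"prevalences for {name!r} must be in [0, 1]")


@dataclass
class SyntheticCohorts:
    pos: CompoundCohort
    neg: CompoundCohort
    #: realized per-alert molecule counts: columns n_pos, n_neg
    realized: pd.DataFrame


def generate_cohorts(
    spec: CohortSpec, dictionary: list[AlertDefinition]
) -> SyntheticCohorts:
    """Assemble two cohorts with Bernoulli-planted alerts.

    Every alert named in ``spec.prevalences`` must exist in the
    dictionary and have a registered carrier; every generated molecule
    is verified against the *whole* dictionary and re-drawn if a
    planted alert fails to match or an unplanted one matches.
    """
    by_name = {a.name: a for a in dictionary}
    for name in spec.prevalences:
        if name not in by_name:
            raise ValueError(f"alert {name!r} not present in the dictionary")
        if name not in spec.carriers:
            raise ValueError(f"no carrier fragment registered for alert {name!r}")
    rng = np.random.default_rng(spec.seed)
    names = sorted(spec.prevalences)
    counts = {name: {"n_pos": 0, "n_neg": 0} for name in names}

    def build(label: str, index: int, p_index: int) -> MoleculeRecord:
        for _attempt in range(50):
            planted = {
                name
                for name in names
                if rng.random() < spec.prevalences[name][p_index]
            }
            expected = set(planted)
            for name in planted:
                expected.update(spec.implies.get(name, []))
            branches = [spec.carriers[name] for name in sorted(planted)]
            scaffold = spec.scaffolds[int(rng.integers(len(spec.scaffolds)))]
            smiles = "".join(f"C({br})" for br in branches) + scaffold
            rec_id = f"{label[:3]}_{index:04d}"
            mol = mol_from_smiles(smiles, rec_id)
            ok = all(
                match_alert(mol, alert) == (alert.name in expected)
                for alert in dictionary
            )
            if ok:
                key = "n_pos" if label == "positive" else "n_neg"
                for name in names:
                    if name in expected:
                        counts[name][key] += 1
                return MoleculeRecord(
                    id=rec_id, name="", mol=mol, label=label  # type: ignore[arg-type]
                )
        raise RuntimeError(
            "could not assemble a molecule consistent with the dictionary; "
            "a carrier fragment probably triggers an unplanted alert "
            "(use spec.implies for subordinate alerts)"
        )

    pos_records = [build("positive", i, 0) for i in range(spec.n_pos)]
    neg_records = [build("negative", i, 1) for i in range(spec.n_neg)]
    realized = pd.DataFrame(counts).T
    realized.index.name = "alert_name"
    return SyntheticCohorts(
        pos=CompoundCohort(pos_records, "positive"),
        neg=CompoundCohort(neg_records, "negative"),
        realized=realized,
    )


# ---------------------------------------------------------------------------
# drug–event report tables

BACKGROUND_DRUG = "__background__"
OTHER_EVENT = "__other__"


@dataclass
class DrugRorSpec:
    drug_id: str
    true_ror: float
    n_exposed: int

    def __post_init__(self) -> None:
        if self.true_ror <= 0:
            raise ValueError("true ROR must be > 0")
        if self.n_exposed < 1:
            raise ValueError("n_exposed must be >= 1")


@dataclass
class ReportTableSpec:
    drugs: list[DrugRorSpec]
    total_cases: int = 10_000
    background_rate: float = 0.05
    event_id: str = "QT_prolongation"
    seed: int = 0
    #: sample the event cells binomially instead of planting them
    sample: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.background_rate < 1:
            raise ValueError("background_rate must be in (0, 1)")
        n_exposed = sum(d.n_exposed for d in self.drugs)
        if n_exposed >= self.total_cases:
            raise ValueError("exposed cases exceed the case universe")


@dataclass
class ReportTableTruth:
    tables: dict[str, ContingencyTable]
    planted_ror: dict[str, float]
    realized_ror: dict[str, float]


def generate_report_table(spec: ReportTableSpec) -> tuple[pd.DataFrame, ReportTableTruth]:
    """Case-level drug–event records with exactly known per-drug tables.

    Each case lists one drug (or the background placeholder) and one
    event (the studied event or a neutral placeholder), so aggregating
    with ``build_contingency`` reproduces the constructed cells exactly.
    """
    rng = np.random.default_rng(spec.seed)
    n_unexposed = spec.total_cases - sum(d.n_exposed for d in spec.drugs)
    p0 = spec.background_rate
    if spec.sample:
        e_bg = int(rng.binomial(n_unexposed, p0))
        odds0 = p0 / (1 - p0)
        a_cells = {
            d.drug_id: int(
                rng.binomial(d.n_exposed, (d.true_ror * odds0) / (1 + d.true_ror * odds0))
            )
            for d in spec.drugs
        }
    else:
        e_bg = round(n_unexposed * p0)
        a_cells = {d.drug_id: 0 for d in spec.drugs}
        # cells are coupled through the shared event margin; a few
        # fixed-point passes settle the integers
        for _ in range(20):
            changed = False
            for d in spec.drugs:
                others = sum(v for k, v in a_cells.items() if k != d.drug_id)
                c = e_bg + others
                dd = (spec.total_cases - d.n_exposed) - c
                if c <= 0 or dd <= 0:
                    raise ValueError("infeasible cell counts for the given spec")
                rho = d.true_ror * c / dd
                a_new = int(round(d.n_exposed * rho / (1 + rho)))
                a_new = min(max(a_new, 0), d.n_exposed)
                if a_new != a_cells[d.drug_id]:
                    a_cells[d.drug_id] = a_new
                    changed = True
            if not changed:
                break

    rows: list[tuple[str, str, str]] = []
    case = 0
    tables: dict[str, ContingencyTable] = {}
    total_a = sum(a_cells.values())
    for d in spec.drugs:
        a = a_cells[d.drug_id]
        b = d.n_exposed - a
        for _ in range(a):
            rows.append((f"case{case:07d}", d.drug_id, spec.event_id))
            case += 1
        for _ in range(b):
            rows.append((f"case{case:07d}", d.drug_id, OTHER_EVENT))
            case += 1
    for _ in range(e_bg):
        rows.append((f"case{case:07d}", BACKGROUND_DRUG, spec.event_id))
        case += 1
    for _ in range(n_unexposed - e_bg):
        rows.append((f"case{case:07d}", BACKGROUND_DRUG, OTHER_EVENT))
        case += 1

    realized: dict[str, float] = {}
    for d in spec.drugs:
        a = a_cells[d.drug_id]
        b = d.n_exposed - a
        c = (total_a - a) + e_bg
        dd = spec.total_cases - a - b - c
        tables[d.drug_id] = ContingencyTable(a, b, c, dd)
        realized[d.drug_id] = (a * dd) / (b * c) if b * c else float("inf")

    records = pd.DataFrame(rows, columns=["case_id", "drug_id", "event_id"])
    truth = ReportTableTruth(
        tables=tables,
        planted_ror={d.drug_id: d.true_ror for d in spec.drugs},
        realized_ror=realized,
    )
    return records, truth


def report_table_from_cells(
    drug_id: str, a: int, b: int, c: int, d: int, event_id: str = "QT_prolongation"
) -> pd.DataFrame:
    """Single-drug records reproducing the given cells exactly."""
    rows = (
        [(drug_id, event_id)] * a
        + [(drug_id, OTHER_EVENT)] * b
        + [(BACKGROUND_DRUG, event_id)] * c
        + [(BACKGROUND_DRUG, OTHER_EVENT)] * d
    )
    return pd.DataFrame(
        [(f"case{i:07d}", dr, ev) for i, (dr, ev) in enumerate(rows)],
        columns=["case_id", "drug_id", "event_id"],
    )


# ---------------------------------------------------------------------------
# class-signal descriptor matrices


@dataclass
class SignalMatrixSpec:
    n_pos: int = 144
    n_neg: int = 95
    n_informative: int = 10
    effect_size: float = 1.0  # class mean separation in units of the feature sd
    n_noise: int = 40
    seed: int = 0
    informative_codes: list[str] | None = None

    def __post_init__(self) -> None:
        if self.n_informative < 0 or self.n_noise < 0:
            raise ValueError("feature counts must be >= 0")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect size must be finite")
        if self.informative_codes is not None and len(self.informative_codes) != self.n_informative:
            raise ValueError("informative_codes length must equal n_informative")


@dataclass
class SignalMatrixTruth:
    informative: list[str]
    effect_size: float
    bayes_error_mc: float  # Monte-Carlo estimate under the generating model


def generate_signal_matrix(spec: SignalMatrixSpec) -> tuple[DescriptorMatrix, SignalMatrixTruth]:
    """Two-class Gaussian matrix: informative columns have class means
    at ±effect_size/2, noise columns are class-independent N(0,1)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_pos + spec.n_neg
    p = spec.n_informative + spec.n_noise
    y = np.array([1] * spec.n_pos + [0] * spec.n_neg)
    X = rng.standard_normal((n, p))
    delta = spec.effect_size
    X[: spec.n_pos, : spec.n_informative] += delta / 2
    X[spec.n_pos :, : spec.n_informative] -= delta / 2

    if spec.informative_codes is not None:
        inf_codes = list(spec.informative_codes)
    else:
        inf_codes = [f"S{i + 1:03d}" for i in range(spec.n_informative)]
    codes = inf_codes + [f"X{i + 1:03d}" for i in range(spec.n_noise)]
    ids = [f"mol_{i:04d}" for i in range(n)]
    values = pd.DataFrame(X, index=pd.Index(ids, name="id"), columns=codes)
    labels = pd.Series(
        np.where(y == 1, "positive", "negative"), index=values.index, name="label"
    )

    # Bayes rule for equal-covariance Gaussians is linear along the
    # shift vector; estimate its error by simulation, honoring the
    # class priors implied by the cohort sizes.
    pi1 = spec.n_pos / n
    if spec.n_informative == 0 or delta == 0:
        bayes = min(pi1, 1 - pi1)
    else:
        m = 200_000
        sim_rng = np.random.default_rng(spec.seed + 1)
        y_sim = sim_rng.random(m) < pi1
        # sufficient statistic: projection onto the shift direction
        mu = delta / 2 * np.sqrt(spec.n_informative)
        t = sim_rng.standard_normal(m) + np.where(y_sim, mu, -mu)
        # LLR threshold from the priors
        thresh = np.log((1 - pi1) / pi1) / (2 * mu)
        pred = t > thresh
        bayes = float(np.mean(pred != y_sim))
    truth = SignalMatrixTruth(
        informative=inf_codes, effect_size=delta, bayes_error_mc=bayes
    )
    return DescriptorMatrix(values, labels), truth
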