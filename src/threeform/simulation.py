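"""Synthetic population and the Monte-Carlo resampling study driver.

The population emulates an exercise-psychology survey: three correlated
latent constructs — ego-involving climate (13 items), task-involving climate
(14 items), and caring climate (13 items) — measured by quasi-continuous
items under a linear one-factor-per-scale model, plus demographic columns
(sex, age, race) and a small completely-at-random extant missingness rate.

The study crosses three factors: the X-block composition (trivial =
demographics only; informed = demographics plus a fixed configured item
list standing in for theory-driven choices; random = demographics plus
randomly chosen scale items), the A/B/C assignment (within-block,
between-block, or random allotment), and the sample size.  The combination
random X-block + random allotment is the RIA condition.  Each replication
bootstraps N=500 participants from the population, recursively trims to the
smaller sizes, fits the analysis model to the untouched sample (the
complete-data control, which defines the "true" values), then imposes each
design, imputes, parcels, fits, and pools.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import metrics
from .design import BlockAllocation, FormSet, build_forms
from .estimator import (
    build_parcels,
    draw_imputations,
    em_mvn,
    fit_parcel_cfa,
    round_robin_parcels,
    rubin_pool,
)
from .exceptions import InvalidInputError, InvalidSpecError
from .metrics import FailureCategory
from .missingness import assign_forms, impose_missingness

DEMOGRAPHICS = ("sex", "age", "race")


@dataclass
class PopulationModel:
    """Generating model for the synthetic population.

    Items follow ``y = intercept + loading * eta + e`` with standardized
    latent constructs (unit variances, correlations ``latent_corr``) and
    independent normal residuals.  Demographics are generated from the
    printed marginals of the emulated study sample (98.5% female, age mean
    49.27 / SD 11.09, 90.2% white) with no joint structure.  ``extant_rate``
    is the per-cell MCAR probability of naturally occurring missingness.
    With ``ordinal=True`` items are discretized onto a 1..5 scale with
    roughly symmetric category margins.
    """

    scales: dict[str, tuple[str, ...]]
    loadings: dict[str, np.ndarray]
    intercepts: dict[str, np.ndarray]
    residual_variances: dict[str, np.ndarray]
    latent_corr: np.ndarray
    extant_rate: float = 0.005
    ordinal: bool = False
    informed_x: tuple[str, ...] | None = None
    prop_female: float = 0.985
    age_mean: float = 49.27
    age_sd: float = 11.09
    prop_white: float = 0.902

    def __post_init__(self):
        self.latent_corr = np.asarray(self.latent_corr, dtype=float)
        k = len(self.scales)
        if self.latent_corr.shape != (k, k):
            raise InvalidSpecError("latent correlation matrix shape must match scale count")
        if not np.allclose(np.diag(self.latent_corr), 1.0):
            raise InvalidSpecError("latent correlation matrix must have a unit diagonal")
        if not np.allclose(self.latent_corr, self.latent_corr.T):
            raise InvalidSpecError("latent correlation matrix must be symmetric")
        if np.linalg.eigvalsh(self.latent_corr).min() <= 0:
            raise InvalidSpecError("latent correlation matrix must be positive definite")
        if not 0.0 <= self.extant_rate <= 0.05:
            raise InvalidSpecError("extant missingness rate must lie in [0, 0.05]")
        for sid, items in self.scales.items():
            P = len(items)
            for name, d in (
                ("loadings", self.loadings),
                ("intercepts", self.intercepts),
                ("residual_variances", self.residual_variances),
            ):
                d[sid] = np.asarray(d[sid], dtype=float)
                if d[sid].shape != (P,):
                    raise InvalidSpecError(f"{name}[{sid!r}] must have length {P}")
            if (self.residual_variances[sid] < 0).any():
                raise InvalidSpecError("residual variances must be nonnegative")

    @property
    def scale_ids(self) -> tuple[str, ...]:
        return tuple(self.scales)

    @property
    def item_columns(self) -> tuple[str, ...]:
        return tuple(it for items in self.scales.values() for it in items)

    @property
    def columns(self) -> tuple[str, ...]:
        return self.item_columns + DEMOGRAPHICS

    def informed_x_items(self) -> tuple[str, ...]:
        """The informed-proxy X-block items: by default the highest-loading
        item of each scale (a stand-in for theory-driven selection)."""
        if self.informed_x is not None:
            return self.informed_x
        return tuple(
            items[int(np.argmax(self.loadings[sid]))] for sid, items in self.scales.items()
        )

    def parcel_map(self) -> dict[str, list[list[str]]]:
        """Canonical round-robin three-parcel partition of each scale."""
        return {sid: round_robin_parcels(items) for sid, items in self.scales.items()}

    def true_parameters(self) -> dict[str, float]:
        """Population values of the analysis-model parameters (parcel scale)."""
        out: dict[str, float] = {}
        for sid, items in self.scales.items():
            groups = round_robin_parcels(items)
            pos = {it: k for k, it in enumerate(items)}
            lam_parcel = []
            theta_parcel = []
            for k, group in enumerate(groups, start=1):
                idx = [pos[it] for it in group]
                lam_parcel.append(float(np.mean(self.loadings[sid][idx])))
                theta_parcel.append(
                    float(np.sum(self.residual_variances[sid][idx]) / len(idx) ** 2)
                )
            for k, (l, t) in enumerate(zip(lam_parcel, theta_parcel), start=1):
                out[f"loading[{sid},p{k}]"] = l
                out[f"residual[{sid},p{k}]"] = t
            out[f"reliability[{sid}]"] = metrics.latent_reliability(
                lam_parcel, 1.0, theta_parcel
            )
        ids = self.scale_ids
        for a in range(len(ids)):
            for b in range(a + 1, len(ids)):
                out[f"latcor[{ids[a]},{ids[b]}]"] = float(self.latent_corr[a, b])
        return out


def default_population(extant_rate: float = 0.005, ordinal: bool = False) -> PopulationModel:
    """The default three-scale population (13 / 14 / 13 items).

    Loadings are evenly spaced in [0.45, 0.85] within each scale, residual
    variances make unit item variances, intercepts sit around the scale
    midpoint of a five-point response format, and the latent correlations
    are (ego, task) = -0.30, (ego, caring) = -0.25, (task, caring) = 0.60.
    """
    sizes = {"ego": 13, "task": 14, "caring": 13}
    scales = {
        sid: tuple(f"{sid}{i + 1:02d}" for i in range(P)) for sid, P in sizes.items()
    }
    loadings = {sid: np.linspace(0.45, 0.85, P) for sid, P in sizes.items()}
    residuals = {sid: 1.0 - loadings[sid] ** 2 for sid in sizes}
    intercepts = {sid: np.linspace(2.6, 3.4, P) for sid, P in sizes.items()}
    phi = np.array(
        [
            [1.0, -0.30, -0.25],
            [-0.30, 1.0, 0.60],
            [-0.25, 0.60, 1.0],
        ]
    )
    return PopulationModel(
        scales=scales,
        loadings=loadings,
        intercepts=intercepts,
        residual_variances=residuals,
        latent_corr=phi,
        extant_rate=extant_rate,
        ordinal=ordinal,
    )


def simulate_population(
    model: PopulationModel,
    N: int,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Draw N participants from the generating model."""
    if N < 1:
        raise InvalidSpecError("N must be at least 1")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    k = len(model.scales)
    chol = np.linalg.cholesky(model.latent_corr)
    eta = rng.standard_normal((N, k)) @ chol.T

    data: dict[str, np.ndarray] = {}
    for j, (sid, items) in enumerate(model.scales.items()):
        lam = model.loadings[sid]
        theta = model.residual_variances[sid]
        nu = model.intercepts[sid]
        y = nu + np.outer(eta[:, j], lam) + rng.standard_normal((N, len(items))) * np.sqrt(theta)
        if model.ordinal:
            sd = np.sqrt(lam**2 + theta)
            edges = nu + np.array([-1.5, -0.5, 0.5, 1.5])[:, None] * sd  # (4, P)
            y = 1.0 + (y[:, None, :] > edges[None, :, :]).sum(axis=1)
        for i, it in enumerate(items):
            data[it] = y[:, i]

    data["sex"] = (rng.random(N) < model.prop_female).astype(float)
    data["age"] = model.age_mean + model.age_sd * rng.standard_normal(N)
    data["race"] = (rng.random(N) < model.prop_white).astype(float)

    df = pd.DataFrame(data, columns=list(model.columns))
    if model.extant_rate > 0:
        mask = rng.random(df.shape) < model.extant_rate
        df = df.mask(pd.DataFrame(mask, index=df.index, columns=df.columns))
    return df


def resample_and_trim(
    population: pd.DataFrame,
    sizes: Sequence[int],
    rng: np.random.Generator | int | None = None,
) -> list[pd.DataFrame]:
    """A bootstrap sample at the largest size, then nested random trims.

    The first sample is drawn with replacement from the population; each
    subsequent sample removes uniformly random rows from the previous one,
    so the samples are nested (row identifiers of a smaller sample are a
    subset of its parent's).
    """
    sizes = list(sizes)
    if not sizes or sizes[0] < 1:
        raise InvalidSpecError("the largest sample size must be positive")
    if any(b >= a for a, b in zip(sizes, sizes[1:])):
        raise InvalidSpecError("sizes must be strictly decreasing for trimming")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    idx = rng.integers(0, len(population), size=sizes[0])
    current = population.iloc[idx].reset_index(drop=True)
    out = [current]
    for s in sizes[1:]:
        keep = np.sort(rng.choice(current.index.to_numpy(), size=s, replace=False))
        current = current.loc[keep]
        out.append(current)
    return out


@dataclass
class StudyConfig:
    """Factor levels and scale of the resampling study.

    The full crossed design is ``x_levels x parcel_levels x sizes``; the
    defaults give the 3 x 3 x 5 = 45-condition grid.  ``reps`` and
    ``imputations`` default to a desk-scale profile (R=50, M=20); the
    emulated study's scale (R=495, M=100) is reachable by configuration.
    """

    x_levels: tuple[str, ...] = ("trivial", "informed", "random")
    parcel_levels: tuple[str, ...] = ("within", "between", "random")
    sizes: tuple[int, ...] = (500, 400, 300, 200, 100)
    reps: int = 50
    imputations: int = 20
    p_x: int = 4
    population_size: int = 5244
    assignment_mode: str = "balanced"
    em_tol: float = 1e-6
    em_max_iter: int = 500
    seed: Optional[int] = None

    def __post_init__(self):
        if not self.x_levels or not self.parcel_levels or not self.sizes:
            raise InvalidSpecError("factor levels and sizes must be nonempty")
        bad = set(self.x_levels) - {"trivial", "informed", "random"}
        if bad:
            raise InvalidSpecError(f"unknown X-block levels: {sorted(bad)}")
        bad = set(self.parcel_levels) - {"within", "between", "random"}
        if bad:
            raise InvalidSpecError(f"unknown parcel levels: {sorted(bad)}")
        if any(b >= a for a, b in zip(self.sizes, self.sizes[1:])):
            raise InvalidSpecError("sizes must be strictly decreasing")

    @property
    def conditions(self) -> list[tuple[str, str]]:
        return list(itertools.product(self.x_levels, self.parcel_levels))

    @property
    def grid_size(self) -> int:
        return len(self.x_levels) * len(self.parcel_levels) * len(self.sizes)


@dataclass
class StudyResult:
    """Long-format estimates plus the per-condition failure log."""

    records: pd.DataFrame  # condition, x_level, parcel_level, n, rep, parameter, estimate, se
    failures: pd.DataFrame  # condition, n, rep, category
    config: StudyConfig

    def tally(self, condition: str, n: int) -> metrics.FailureTally:
        tally = metrics.FailureTally()
        sel = self.failures[(self.failures["condition"] == condition) & (self.failures["n"] == n)]
        by_rep = dict(zip(sel["rep"], sel["category"]))
        ok = self.records[
            (self.records["condition"] == condition) & (self.records["n"] == n)
        ]
        reps = sorted(set(ok["rep"]).union(sel["rep"]))
        for rep in reps:
            cat = by_rep.get(rep)
            tally.record(FailureCategory(cat) if cat is not None else None)
        return tally


def _abc_split(n: int, rng: np.random.Generator) -> dict[str, int]:
    base, rem = divmod(n, 3)
    counts = {"A": base, "B": base, "C": base}
    if rem:
        for i in rng.choice(3, size=rem, replace=False):
            counts[("A", "B", "C")[i]] += 1
    return counts


def condition_allocation(
    model: PopulationModel,
    x_level: str,
    parcel_level: str,
    p_x: int,
    rng: np.random.Generator,
) -> BlockAllocation:
    """Build the block allocation for one design condition.

    X-block: demographics always, plus — per ``x_level`` — nothing
    (``trivial``), the fixed informed-proxy list (``informed``), or ``p_x``
    scale items chosen uniformly at random ignoring scale membership
    (``random``).  The remaining scale items go to A/B/C per
    ``parcel_level``: ``random`` pools them and allots uniformly at random
    (with the random X-block this is the RIA condition); ``between`` spreads
    each round-robin parcel's items across A, B, and C; ``within`` assigns
    each parcel's items wholly to one random block.
    """
    if x_level == "trivial":
        x_items: set[str] = set()
    elif x_level == "informed":
        x_items = set(model.informed_x_items())
    elif x_level == "random":
        pool = list(model.item_columns)
        x_items = set(rng.choice(pool, size=p_x, replace=False))
    else:
        raise InvalidSpecError(f"unknown X-block level {x_level!r}")

    assignment: dict[str, str] = {}
    provenance: dict[str, str] = {}
    for it in model.item_columns:
        if it in x_items:
            assignment[it] = "X"
            provenance[it] = f"x-{x_level}"

    if parcel_level == "random":
        remaining = [it for it in model.item_columns if it not in x_items]
        counts = _abc_split(len(remaining), rng)
        order = rng.permutation(len(remaining))
        pos = 0
        labels: dict[str, str] = {}
        for b in ("A", "B", "C"):
            for k in order[pos : pos + counts[b]]:
                labels[remaining[k]] = b
            pos += counts[b]
        for it in remaining:
            assignment[it] = labels[it]
            provenance[it] = "ria"
    elif parcel_level in ("between", "within"):
        for sid, items in model.scales.items():
            for group in round_robin_parcels(items):
                group = [it for it in group if it not in x_items]
                if not group:
                    continue
                if parcel_level == "within":
                    blk = ("A", "B", "C")[rng.integers(3)]
                    for it in group:
                        assignment[it] = blk
                        provenance[it] = "within"
                else:
                    order3 = [("A", "B", "C")[i] for i in rng.permutation(3)]
                    for k, it in enumerate(group):
                        assignment[it] = order3[k % 3]
                        provenance[it] = "between"
    else:
        raise InvalidSpecError(f"unknown parcel level {parcel_level!r}")

    for d in DEMOGRAPHICS:
        assignment[d] = "X"
        provenance[d] = "demographic"

    ordered = {it: assignment[it] for it in model.columns}
    return BlockAllocation(ordered, {it: provenance[it] for it in model.columns})


def estimate_sample(
    sample: pd.DataFrame,
    model: PopulationModel,
    config: StudyConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, tuple[float, float]], Optional[FailureCategory]]:
    """EM -> M imputations -> parcels -> per-scale CFA -> Rubin pooling.

    Returns parameter -> (estimate, SE) and a failure category (None when
    clean).  An inadmissible (Heywood) fit in any imputation flags the
    replication but the pooled estimates are still returned so callers can
    inspect them; summaries exclude flagged replications.
    """
    failure: Optional[FailureCategory] = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est = em_mvn(sample, tol=config.em_tol, max_iter=config.em_max_iter)
    if not est.converged:
        return {}, FailureCategory.IMPUTATION
    imps = draw_imputations(sample, est, config.imputations, rng)

    parcel_map = model.parcel_map()
    parcel_cols = {sid: [f"{sid}_p{k}" for k in (1, 2, 3)] for sid in model.scale_ids}
    n = len(sample)
    per_imp_est: list[dict[str, float]] = []
    per_imp_var: list[dict[str, float]] = []
    any_inadmissible = False
    all_converged = True
    for imp in imps:
        try:
            parcels = build_parcels(imp[list(model.item_columns)], parcel_map)
            S = parcels.cov()
            fit = fit_parcel_cfa(S, n, parcel_cols)
        except Exception:
            return {}, FailureCategory.NONCONVERGENCE
        any_inadmissible |= not fit.admissible
        all_converged &= fit.converged
        e = dict(fit.estimates)
        v = dict(fit.variances)
        means = parcels.mean()
        for c in parcels.columns:
            e[f"intercept[{c}]"] = float(means[c])
            v[f"intercept[{c}]"] = float(S.loc[c, c] / n)
        for sid in model.scale_ids:
            lam = np.array([fit.estimates[f"loading[{sid},p{k}]"] for k in (1, 2, 3)])
            theta = np.array([fit.estimates[f"residual[{sid},p{k}]"] for k in (1, 2, 3)])
            tv = lam.sum() ** 2
            e[f"reliability[{sid}]"] = float(tv / (tv + theta.sum()))
            v[f"reliability[{sid}]"] = np.nan
        per_imp_est.append(e)
        per_imp_var.append(v)

    if not all_converged:
        failure = FailureCategory.NONCONVERGENCE
    elif any_inadmissible:
        failure = FailureCategory.INADMISSIBLE

    names = list(per_imp_est[0])
    out: dict[str, tuple[float, float]] = {}
    q = np.array([[e[nm] for nm in names] for e in per_imp_est])
    u = np.array([[v[nm] for v in per_imp_var] for nm in names]).T
    has_var = ~np.isnan(u).any(axis=0)
    pooled = rubin_pool(q[:, has_var], u[:, has_var])
    j = 0
    for i, nm in enumerate(names):
        if has_var[i]:
            out[nm] = (float(pooled.estimate[j]), float(pooled.se[j]))
            j += 1
        else:
            out[nm] = (float(q[:, i].mean()), np.nan)
    return out, failure


def run_condition(
    sample: pd.DataFrame,
    x_level: str,
    parcel_level: str,
    config: StudyConfig,
    model: PopulationModel,
    rng: np.random.Generator,
) -> tuple[dict[str, tuple[float, float]], Optional[FailureCategory]]:
    """Impose one design condition on a sample and estimate the model.

    A fresh random allocation (and form assignment) is drawn on every call,
    so random-level conditions get a new random design each replication.
    Stage failures are mapped onto the four failure categories and recorded,
    never raised.
    """
    try:
        alloc = condition_allocation(model, x_level, parcel_level, config.p_x, rng)
        formset = build_forms(alloc)
        assignment = assign_forms(len(sample), config.assignment_mode, rng)
        masked = impose_missingness(sample, formset, assignment)
    except Exception:
        return {}, FailureCategory.COMPLETE
    try:
        return estimate_sample(masked, model, config, rng)
    except Exception:
        return {}, FailureCategory.IMPUTATION


def run_study(config: StudyConfig, model: PopulationModel | None = None) -> StudyResult:
    """Run the full crossed resampling study.

    The complete-data control is estimated once per (replication, size) and
    shared across all design conditions at that size; it defines the "true"
    values for bias and the complete-data SE series for relative efficiency.
    Fully reproducible under a fixed ``config.seed``.
    """
    if model is None:
        model = default_population()
    master = int(config.seed) if config.seed is not None else 0
    pop_rng = np.random.default_rng(np.random.SeedSequence([master, 0]))
    population = simulate_population(model, config.population_size, pop_rng)

    rows: list[dict] = []
    fail_rows: list[dict] = []
    conditions = config.conditions
    for rep in range(config.reps):
        boot_rng = np.random.default_rng(np.random.SeedSequence([master, 1, rep]))
        samples = resample_and_trim(population, config.sizes, boot_rng)
        for size, sample in zip(config.sizes, samples):
            ctrl_rng = np.random.default_rng(np.random.SeedSequence([master, 2, rep, size]))
            try:
                ctrl, ctrl_fail = estimate_sample(sample, model, config, ctrl_rng)
            except Exception:
                ctrl, ctrl_fail = {}, FailureCategory.COMPLETE
            _collect(rows, fail_rows, "control", None, None, size, rep, ctrl, ctrl_fail)
            for k, (x_level, parcel_level) in enumerate(conditions):
                crng = np.random.default_rng(
                    np.random.SeedSequence([master, 3, rep, size, k])
                )
                res, fail = run_condition(sample, x_level, parcel_level, config, model, crng)
                label = f"{x_level}/{parcel_level}"
                _collect(rows, fail_rows, label, x_level, parcel_level, size, rep, res, fail)

    records = pd.DataFrame(
        rows,
        columns=["condition", "x_level", "parcel_level", "n", "rep", "parameter", "estimate", "se"],
    )
    failures = pd.DataFrame(fail_rows, columns=["condition", "n", "rep", "category"])
    return StudyResult(records=records, failures=failures, config=config)


def _collect(rows, fail_rows, condition, x_level, parcel_level, size, rep, res, fail):
    if fail is not None:
        fail_rows.append(
            {"condition": condition, "n": size, "rep": rep, "category": int(fail)}
        )
        return
    for name, (est, se) in res.items():
        rows.append(
            {
                "condition": condition,
                "x_level": x_level,
                "parcel_level": parcel_level,
                "n": size,
                "rep": rep,
                "parameter": name,
                "estimate": est,
                "se": se,
            }
        )


def _param_class(name: str) -> str:
    return name.split("[", 1)[0]


def summarize(
    result: StudyResult,
    prb_threshold: float = metrics.DEFAULT_PRB_THRESHOLD,
    class_means: bool = True,
) -> pd.DataFrame:
    """RE and PRB per condition, sample size, and parameter.

    Truth is the replication-average complete-data (control) estimate at the
    same sample size; RE pairs each replication's control SE with the
    condition SE.  Replications that failed in either arm are excluded.
    Rows with ``parameter`` of the form ``class:<name>`` are unweighted
    means over the parameters of that class, labeled as such.
    """
    rec = result.records
    ctrl = rec[rec["condition"] == "control"]
    if ctrl.empty:
        raise InvalidInputError("result contains no complete-data control records")
    out: list[dict] = []
    for condition in rec["condition"].unique():
        sub = rec[rec["condition"] == condition]
        for n in sorted(sub["n"].unique(), reverse=True):
            sub_n = sub[sub["n"] == n]
            ctrl_n = ctrl[ctrl["n"] == n]
            merged = sub_n.merge(
                ctrl_n[["rep", "parameter", "estimate", "se"]],
                on=["rep", "parameter"],
                suffixes=("", "_ctrl"),
            )
            for param, grp in merged.groupby("parameter", sort=True):
                truth = float(grp["estimate_ctrl"].mean())
                entry = {
                    "condition": condition,
                    "n": n,
                    "parameter": param,
                    "class": _param_class(param),
                    "n_reps": len(grp),
                }
                if truth != 0:
                    prb = metrics.percent_relative_bias(grp["estimate"].to_numpy(), truth)
                    out.append(
                        {**entry, "statistic": "PRB", "value": prb,
                         "flag": metrics.prb_flag(prb, prb_threshold)}
                    )
                ok = grp["se"].notna() & grp["se_ctrl"].notna() & (grp["se"] > 0)
                if ok.any():
                    re_val = metrics.relative_efficiency(
                        grp.loc[ok, "se_ctrl"].to_numpy(), grp.loc[ok, "se"].to_numpy()
                    )
                    out.append({**entry, "statistic": "RE", "value": re_val, "flag": False})
    table = pd.DataFrame(out)
    if class_means and not table.empty:
        cm = (
            table.groupby(["condition", "n", "class", "statistic"], sort=False)["value"]
            .mean()
            .reset_index()
        )
        cm["parameter"] = "class:" + cm["class"]
        cm["n_reps"] = np.nan
        cm["flag"] = (cm["statistic"] == "PRB") & (cm["value"].abs() > prb_threshold)
        table = pd.concat([table, cm[table.columns]], ignore_index=True)
    return table
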