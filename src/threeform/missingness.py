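"""Form assignment, planned-missingness imposition, and coverage diagnostics.

Data tables are pandas DataFrames (participants x items) with NaN marking
missing cells.  Imposing a three-form design blanks out, for each
participant, the items absent from the form they were assigned; cells that
were already missing stay missing, so planned and extant missingness
coexist.  The missingness introduced this way is MCAR by construction: form
assignment ignores every variable in the table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import FORM_LABELS, FormSet
from .exceptions import InvalidInputError, SchemaError


def assign_forms(
    n: int,
    mode: str = "balanced",
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Randomly assign ``n`` participants to the three forms.

    ``balanced`` (the default) permutes a maximally even label vector so the
    per-form counts differ by at most one; ``iid`` draws each participant's
    form independently and uniformly, mirroring what typical web-survey
    randomizers do.
    """
    if n < 0:
        raise InvalidInputError("participant count must be nonnegative")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    labels = np.asarray(FORM_LABELS, dtype=object)
    if mode == "iid":
        return labels[rng.integers(3, size=n)]
    if mode != "balanced":
        raise InvalidInputError(f"mode must be 'balanced' or 'iid', got {mode!r}")
    base, rem = divmod(n, 3)
    counts = np.full(3, base)
    if rem:
        counts[rng.choice(3, size=rem, replace=False)] += 1
    vec = np.repeat(labels, counts)
    return vec[rng.permutation(n)]


def impose_missingness(
    data: pd.DataFrame,
    formset: FormSet,
    assignment: np.ndarray | pd.Series,
) -> pd.DataFrame:
    """Blank out, per participant, the design items absent from their form.

    Columns of ``data`` that do not appear on any form (e.g. bookkeeping
    columns) pass through untouched; pre-existing missing cells are retained.
    The operation is idempotent for a fixed formset/assignment.
    """
    design_items = set(formset.items())
    missing_cols = design_items - set(data.columns)
    if missing_cols:
        raise SchemaError(f"form items absent from the data: {sorted(missing_cols)}")
    assignment = np.asarray(assignment, dtype=object)
    if assignment.shape[0] != len(data):
        raise SchemaError(
            f"assignment length {assignment.shape[0]} != row count {len(data)}"
        )
    bad = set(assignment) - set(FORM_LABELS)
    if bad:
        raise SchemaError(f"unknown form labels in assignment: {sorted(bad)}")

    out = data.copy()
    cols = [c for c in data.columns if c in design_items]
    col_idx = [data.columns.get_loc(c) for c in cols]
    for label in FORM_LABELS:
        rows = np.flatnonzero(assignment == label)
        if rows.size == 0:
            continue
        on_form = set(formset[label])
        drop = [j for c, j in zip(cols, col_idx) if c not in on_form]
        if drop:
            out.iloc[rows, drop] = np.nan
    return out


def enumerate_patterns(data: pd.DataFrame) -> pd.DataFrame:
    """Tabulate the distinct row-wise observed/missing patterns.

    Patterns are keyed by a bitstring over the columns in table order, '1'
    marking an observed cell.  Returns a DataFrame with columns ``pattern``
    and ``count``, most frequent first; counts sum to the row count.
    """
    observed = data.notna().to_numpy()
    if len(data) == 0:
        return pd.DataFrame({"pattern": [], "count": []})
    keys = ["".join("1" if o else "0" for o in row) for row in observed]
    counts = pd.Series(keys).value_counts()
    return pd.DataFrame({"pattern": counts.index, "count": counts.to_numpy()})


def coverage_theoretical(
    formset: FormSet,
    form_proportions: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Covariance coverage implied by a form set and form-assignment weights.

    Entry (i, j) is the total weight of the forms containing both items —
    the expected proportion of participants observing the pair.  With equal
    thirds, X-X pairs get 1, X-A pairs 2/3, and A-B pairs 1/3.
    """
    if form_proportions is None:
        form_proportions = {label: 1.0 / 3.0 for label in FORM_LABELS}
    w = np.array([float(form_proportions.get(label, 0.0)) for label in FORM_LABELS])
    if (w < 0).any():
        raise InvalidInputError("form proportions must be nonnegative")
    if abs(w.sum() - 1.0) > 1e-9:
        raise InvalidInputError("form proportions must sum to 1")
    items = formset.items()
    member = np.array(
        [[it in set(formset[label]) for it in items] for label in FORM_LABELS]
    )  # forms x items
    cov = np.einsum("f,fi,fj->ij", w, member, member)
    return pd.DataFrame(cov, index=items, columns=items)


def coverage_empirical(data: pd.DataFrame) -> pd.DataFrame:
    """Observed covariance coverage: fraction of rows with both cells present."""
    if len(data) == 0:
        raise InvalidInputError("empirical coverage requires at least one row")
    obs = data.notna().to_numpy(dtype=float)
    cov = obs.T @ obs / len(data)
    return pd.DataFrame(cov, index=data.columns, columns=data.columns)
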