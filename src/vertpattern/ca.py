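"""Simple correspondence analysis of malformation × pattern tables.

The contingency table crosses malformation categories (rows, including a
no-malformation row) with vertebral-pattern groups (columns).  The analysis
is the classical SVD of standardised residuals: with correspondence matrix
``P = N / n``, row and column masses ``r`` and ``c``, the matrix
``S = D_r^{-1/2} (P - r c^T) D_c^{-1/2}`` is decomposed as ``U Σ V^T``;
squared singular values are the principal inertias, and principal
coordinates are the mass-rescaled singular vectors scaled by the singular
values.  Total inertia equals Pearson χ² / n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .malformations import ORGAN_SYSTEMS, MalformationRecord

NO_MAL_LABEL = "No-Mal"

FOUR_LEVEL_GROUPS: dict[str, list[str]] = {
    "R_LS": ["R", "LS"],
    "TL_TLLS": ["TL", "TL_LS"],
    "CT_CTLS": ["CT", "CT_LS"],
    "CTTL_CTTLLS": ["CT_TL", "CT_TL_LS"],
}
EIGHT_LEVEL = ["R", "LS", "TL", "TL_LS", "CT", "CT_LS", "CT_TL", "CT_TL_LS"]


class CAError(ValueError):
    pass


@dataclass
class CAResult:
    """Inertia decomposition of one contingency table."""

    row_labels: list[str]
    col_labels: list[str]
    principal_inertias: np.ndarray
    percent_explained: np.ndarray
    row_coords: np.ndarray  # rows × dims, principal coordinates
    col_coords: np.ndarray
    row_masses: np.ndarray
    col_masses: np.ndarray
    singular_values: np.ndarray
    total_inertia: float

    @property
    def n_dims(self) -> int:
        return len(self.principal_inertias)

    @property
    def degenerate(self) -> bool:
        return self.total_inertia < 1e-12

    def coords_frame(self) -> pd.DataFrame:
        dims = [f"dim{i + 1}" for i in range(self.n_dims)]
        rows = pd.DataFrame(self.row_coords, index=self.row_labels, columns=dims)
        rows.insert(0, "kind", "row")
        cols = pd.DataFrame(self.col_coords, index=self.col_labels, columns=dims)
        cols.insert(0, "kind", "column")
        return pd.concat([rows, cols])


def build_contingency(
    patterns: dict[str, str],
    records: dict[str, MalformationRecord],
    grouping: str = "eight_level",
    drop_empty: bool = True,
) -> pd.DataFrame:
    """Cross malformation categories with pattern groups.

    ``patterns`` maps subject id to pattern-class value; ``records`` maps
    subject id to its coded malformation record.  A subject contributes one
    count to every organ-system row it is affected in, and to the
    no-malformation row when no available system is affected; subjects with
    every system non-available are excluded.
    """
    if grouping == "four_level":
        col_of = {p: g for g, members in FOUR_LEVEL_GROUPS.items() for p in members}
        col_labels = list(FOUR_LEVEL_GROUPS)
    elif grouping == "eight_level":
        col_of = {p: p for p in EIGHT_LEVEL}
        col_labels = EIGHT_LEVEL
    else:
        raise CAError(f"unknown grouping {grouping!r}; use 'four_level' or 'eight_level'")

    row_labels = ORGAN_SYSTEMS + [NO_MAL_LABEL]
    table = pd.DataFrame(0, index=row_labels, columns=col_labels, dtype=int)
    for sid, pattern in patterns.items():
        rec = records.get(sid)
        if rec is None or rec.fully_non_available:
            continue
        col = col_of[pattern]
        affected = [s for s in ORGAN_SYSTEMS if rec.affected(s)]
        if affected:
            for s in affected:
                table.loc[s, col] += 1
        else:
            table.loc[NO_MAL_LABEL, col] += 1

    if drop_empty:
        empty_rows = table.index[table.sum(axis=1) == 0]
        if len(empty_rows):
            warnings.warn(
                f"dropping all-zero contingency rows: {list(empty_rows)}", stacklevel=2
            )
            table = table.drop(index=empty_rows)
    return table


def correspondence_analysis(table: pd.DataFrame) -> CAResult:
    """From-scratch simple CA of a labelled nonnegative count table."""
    N = np.asarray(table, dtype=float)
    if N.ndim != 2 or N.shape[0] < 2 or N.shape[1] < 2:
        raise CAError("contingency table must be at least 2×2")
    if (N < 0).any():
        raise CAError("negative counts in contingency table")
    n = N.sum()
    if n <= 0:
        raise CAError("empty contingency table")

    row_tot = N.sum(axis=1)
    col_tot = N.sum(axis=0)
    for labels, totals, what in (
        (table.index, row_tot, "row"),
        (table.columns, col_tot, "column"),
    ):
        zero = [str(lbl) for lbl, t in zip(labels, totals) if t == 0]
        if zero:
            raise CAError(f"all-zero {what}(s) in contingency table: {zero}")

    P = N / n
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)

    k = min(N.shape) - 1
    sv = sv[:k]
    inertias = sv**2
    total = float(inertias.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        percent = 100.0 * inertias / total if total > 0 else np.zeros_like(inertias)

    row_coords = (U[:, :k] * sv) / np.sqrt(r)[:, None]
    col_coords = (Vt[:k].T * sv) / np.sqrt(c)[:, None]

    return CAResult(
        row_labels=[str(i) for i in table.index],
        col_labels=[str(j) for j in table.columns],
        principal_inertias=inertias,
        percent_explained=percent,
        row_coords=row_coords,
        col_coords=col_coords,
        row_masses=r,
        col_masses=c,
        singular_values=sv,
        total_inertia=total,
    )


def orient_result(result: CAResult, anchor_row: str = NO_MAL_LABEL) -> CAResult:
    """Fix the arbitrary SVD signs so the anchor row sits on the negative
    side of each dimension (severity then increases left to right)."""
    if anchor_row not in result.row_labels:
        return result
    i = result.row_labels.index(anchor_row)
    flip = np.where(result.row_coords[i] > 0, -1.0, 1.0)
    result.row_coords = result.row_coords * flip
    result.col_coords = result.col_coords * flip
    return result


def interpret_axis(
    result: CAResult, dim: int = 1, anchor_row: str = NO_MAL_LABEL
) -> dict:
    """Order rows and columns along one dimension after sign anchoring.

    Returns a dict with ``rows`` and ``columns`` as (label, coordinate)
    lists sorted by coordinate, plus a ``degenerate`` flag for tables at
    (or numerically at) independence.
    """
    result = orient_result(result, anchor_row)
    d = dim - 1
    if result.degenerate or d >= result.n_dims:
        return {"rows": [], "columns": [], "degenerate": True}
    rows = sorted(zip(result.row_labels, result.row_coords[:, d]), key=lambda t: t[1])
    cols = sorted(zip(result.col_labels, result.col_coords[:, d]), key=lambda t: t[1])
    return {
        "rows": [(lbl, float(x)) for lbl, x in rows],
        "columns": [(lbl, float(x)) for lbl, x in cols],
        "degenerate": False,
    }


def biplot(result: CAResult, path: str, title: str = "") -> None:
    """Optional symmetric-map biplot (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    def _xy(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        y = coords[:, 1] if coords.shape[1] > 1 else np.zeros(len(coords))
        return coords[:, 0], y

    fig, ax = plt.subplots(figsize=(7, 6))
    ax.axhline(0, color="0.8", lw=0.8)
    ax.axvline(0, color="0.8", lw=0.8)
    for labels, coords, color, marker in (
        (result.row_labels, result.row_coords, "tab:red", "o"),
        (result.col_labels, result.col_coords, "tab:blue", "^"),
    ):
        xs, ys = _xy(coords)
        ax.scatter(xs, ys, c=color, marker=marker)
        for lbl, x, y in zip(labels, xs, ys):
            ax.annotate(lbl, (x, y), color=color, fontsize=8)
    pe = result.percent_explained
    ax.set_xlabel(f"dim 1 ({pe[0]:.1f} %)")
    if len(pe) > 1:
        ax.set_ylabel(f"dim 2 ({pe[1]:.1f} %)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
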