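"""Permutation tests for quartile overrepresentation across analytes.

Asks whether a cell line (or a tumor type) appears in the top or bottom
polarization-score quartile across analytes more often than chance. The
statistic is the membership count: for a cell line, the number of analytes
in which it carries the label; for a tumor type, the total number of
labeled quartile slots occupied by its lines. The null draws, for each
analyte independently, a uniformly random quartile set of the same size
from the unit pool and recomputes the identical statistic; p-values use the
add-one estimator (never zero, minimum 1/(n_perm + 1)) and are BH-adjusted
within each test family (cell lines; each tumor-type grouping separately).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import adjust_fdr

__all__ = [
    "OverrepresentationResult",
    "quartile_membership_statistic",
    "permutation_null_counts",
    "overrepresentation_test",
]


@dataclass
class OverrepresentationResult:
    unit: str
    family: str
    direction: str
    observed_statistic: int
    n_permutations: int
    p_perm: float
    p_adj: float
    seed: int


def quartile_membership_statistic(
    quartile_labels: dict[str, dict[str, str]],
    unit: str,
    direction: str,
    metadata: dict[str, str] | None = None,
) -> int:
    """Observed membership count for one unit.

    ``quartile_labels`` maps analyte -> {cell line -> label in
    {top, bottom, middle}}. Without metadata, ``unit`` is a cell line and
    the statistic counts analytes where it carries ``direction``; with
    metadata (line -> tumor type), ``unit`` is a type and the statistic
    sums over its lines.
    """
    if direction not in ("top", "bottom"):
        raise ValueError("direction must be 'top' or 'bottom'")
    if metadata is None:
        known = {line for labels in quartile_labels.values() for line in labels}
        if unit not in known:
            raise KeyError(f"unknown unit {unit!r}")
        return sum(
            1 for labels in quartile_labels.values() if labels.get(unit) == direction
        )
    lines = {line for line, t in metadata.items() if t == unit}
    if not lines:
        raise KeyError(f"unknown tumor type {unit!r}")
    return sum(
        1
        for labels in quartile_labels.values()
        for line in lines
        if labels.get(line) == direction
    )


def permutation_null_counts(
    n_units: int,
    quartile_size: int,
    n_analytes: int,
    unit_multiplicity: int = 1,
    n_permutations: int = 20_000,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Null distribution of the membership count.

    Each permutation draws, for each analyte independently, a uniformly
    random quartile set of ``quartile_size`` from the ``n_units`` pool, and
    counts how many drawn slots land on a fixed block of
    ``unit_multiplicity`` units (1 for a single cell line; the number of
    lines of a type for tumor types). Expected value is
    n_analytes * quartile_size * multiplicity / n_units.
    """
    if 2 * quartile_size > n_units:
        raise ValueError("quartile_size*2 must be <= n_units")
    if unit_multiplicity > n_units:
        raise ValueError("multiplicity exceeds unit pool")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # top-quartile_size of random uniforms == a uniformly random k-subset
    u = rng.random((n_permutations, n_analytes, n_units))
    kth = np.partition(u, quartile_size - 1, axis=2)[:, :, quartile_size - 1]
    member = u[:, :, :unit_multiplicity] <= kth[:, :, None]
    return member.sum(axis=(1, 2))


def overrepresentation_test(
    quartile_labels: dict[str, dict[str, str]],
    metadata: dict[str, dict[str, str]] | None = None,
    n_permutations_lines: int = 20_000,
    n_permutations_types: int = 5_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation overrepresentation tests for every unit and direction.

    ``metadata`` maps grouping-scheme name -> {cell line -> tumor type}
    (e.g. 4- and 5-category groupings); each scheme is its own BH family,
    as is the cell-line family. p_perm = (1 + #{null >= observed}) /
    (1 + n_permutations).
    """
    analytes = sorted(quartile_labels)
    lines = sorted({line for a in analytes for line in quartile_labels[a]})
    n_units = len(lines)
    sizes = {
        a: sum(1 for v in quartile_labels[a].values() if v == "top") for a in analytes
    }
    k = max(sizes.values())
    n_analytes = len(analytes)
    rng = np.random.default_rng(seed)
    rows = []
    null_line = permutation_null_counts(
        n_units, k, n_analytes, 1, n_permutations_lines, rng
    )
    for direction in ("top", "bottom"):
        for line in lines:
            obs = quartile_membership_statistic(quartile_labels, line, direction)
            p = (1.0 + np.sum(null_line >= obs)) / (1.0 + n_permutations_lines)
            rows.append(
                {
                    "unit": line,
                    "family": "cell_line",
                    "direction": direction,
                    "observed_statistic": obs,
                    "n_permutations": n_permutations_lines,
                    "p_perm": p,
                    "seed": seed,
                }
            )
    for scheme, mapping in (metadata or {}).items():
        missing = [line for line in lines if line not in mapping]
        if missing:
            raise KeyError(f"grouping {scheme!r} missing tumor type for lines {missing}")
        types = sorted(set(mapping.values()))
        null_by_mult: dict[int, np.ndarray] = {}
        for direction in ("top", "bottom"):
            for t in types:
                mult = sum(1 for v in mapping.values() if v == t)
                if mult not in null_by_mult:
                    null_by_mult[mult] = permutation_null_counts(
                        n_units, k, n_analytes, mult, n_permutations_types, rng
                    )
                obs = quartile_membership_statistic(
                    quartile_labels, t, direction, metadata=mapping
                )
                p = (1.0 + np.sum(null_by_mult[mult] >= obs)) / (1.0 + n_permutations_types)
                rows.append(
                    {
                        "unit": t,
                        "family": scheme,
                        "direction": direction,
                        "observed_statistic": obs,
                        "n_permutations": n_permutations_types,
                        "p_perm": p,
                        "seed": seed,
                    }
                )
    df = pd.DataFrame(rows)
    df["p_adj"] = np.nan
    for fam, idx in df.groupby("family").groups.items():
        df.loc[idx, "p_adj"] = adjust_fdr(df.loc[idx, "p_perm"], "bh")
    return df
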