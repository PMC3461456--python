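"""Fisher's-exact association tests between CISs and phenotypes.

All tests run on a binary incidence matrix over libraries: one column per
CIS (does the library have an insertion event inside the CIS interval?)
and one column per phenotype group from the metadata file.  Three test
families are handled separately, each with its own multiple-testing
family size: phenotype x CIS (n_ph * n_cis tests), CIS x CIS
(n_cis*(n_cis-1)/2), and phenotype x phenotype (n_ph*(n_ph-1)/2).
Bonferroni and Benjamini-Hochberg adjustments are applied within each
family.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps
from statsmodels.stats import multitest as _smm

from .events import InsertionEvent
from .scan import CIS

ALL_GROUP = "all"


@dataclass
class PresenceMatrix:
    """libraries x (CIS u phenotype) boolean incidence."""

    data: pd.DataFrame  # bool, index = libraries
    cis_columns: list[str]
    phenotype_columns: list[str]

    @property
    def libraries(self) -> list[str]:
        return list(self.data.index)


@dataclass(frozen=True)
class AssociationResult:
    item_a: str
    item_b: str
    table: tuple[int, int, int, int]  # a=both, b=a only, c=b only, d=neither
    odds_direction: int  # +1 co-occurrence, -1 exclusivity, 0 balanced
    p_raw: float
    p_bonferroni: float
    p_bh: float
    n_tests: int


def cis_column_name(cis: CIS) -> str:
    return f"{cis.chrom}:{cis.start}-{cis.end}"


def build_presence_matrix(
    cis_list: Sequence[CIS],
    events: Sequence[InsertionEvent],
    metadata: Mapping[str, Iterable[str]],
    cis_p_filter: float = 1e-5,
) -> PresenceMatrix:
    """Incidence matrix restricted to CISs with region p below the filter.

    `metadata` maps group name -> member libraries and must include the
    superset group "all", which defines the analysis set; every library
    named in any group must belong to it.
    """
    if ALL_GROUP not in metadata:
        raise ValueError('metadata must include the superset group "all"')
    libraries = sorted(metadata[ALL_GROUP])
    lib_set = set(libraries)
    for group, members in metadata.items():
        unknown = set(members) - lib_set
        if unknown:
            raise ValueError(f"group {group!r} names unknown libraries: {sorted(unknown)}")
    data = pd.DataFrame(index=pd.Index(libraries, name="library"), dtype=bool)
    cis_cols = []
    for cis in cis_list:
        if not cis.p_region < cis_p_filter:
            continue
        name = cis_column_name(cis)
        members = {e.library for e in events
                   if e.chrom == cis.chrom and cis.start <= e.bin_start < cis.end}
        data[name] = [lib in members for lib in libraries]
        cis_cols.append(name)
    pheno_cols = []
    for group in sorted(metadata):
        members = set(metadata[group])
        data[group] = [lib in members for lib in libraries]
        pheno_cols.append(group)
    return PresenceMatrix(data.astype(bool), cis_cols, pheno_cols)


def fisher_exact_2x2(a: int, b: int, c: int, d: int,
                     alternative: str = "two-sided") -> float:
    """Fisher's exact p for the 2x2 table [[a, b], [c, d]]."""
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b + c + d < 1:
        raise ValueError("table must contain at least one observation")
    return float(min(1.0, _sps.fisher_exact([[a, b], [c, d]], alternative=alternative)[1]))


def adjust_pvalues(pvals: Sequence[float], method: str) -> list[float]:
    """Bonferroni or Benjamini-Hochberg adjusted p-values (capped at 1)."""
    if len(pvals) == 0:
        return []
    if method == "bonferroni":
        key = "bonferroni"
    elif method == "bh":
        key = "fdr_bh"
    else:
        raise ValueError(f"unknown method {method!r}")
    return list(_smm.multipletests(np.asarray(pvals, dtype=float), method=key)[1])


def _test_family(matrix: PresenceMatrix, pairs: list[tuple[str, str]],
                 alternative: str) -> list[AssociationResult]:
    if not pairs:
        return []
    tables = []
    raws = []
    for x, y in pairs:
        vx = matrix.data[x].to_numpy()
        vy = matrix.data[y].to_numpy()
        a = int((vx & vy).sum())
        b = int((vx & ~vy).sum())
        c = int((~vx & vy).sum())
        d = int((~vx & ~vy).sum())
        tables.append((a, b, c, d))
        raws.append(fisher_exact_2x2(a, b, c, d, alternative))
    bonf = adjust_pvalues(raws, "bonferroni")
    bh = adjust_pvalues(raws, "bh")
    n = len(pairs)
    results = [
        AssociationResult(x, y, t, int(np.sign(t[0] * t[3] - t[1] * t[2])),
                          p, pb, ph, n)
        for (x, y), t, p, pb, ph in zip(pairs, tables, raws, bonf, bh)
    ]
    results.sort(key=lambda r: (r.p_raw, r.item_a, r.item_b))
    return results


def run_associations(
    matrix: PresenceMatrix,
    alternative: str = "two-sided",
    exclude_columns: Iterable[str] = (ALL_GROUP,),
) -> dict[str, list[AssociationResult]]:
    """All three association families from one incidence matrix.

    The constant-true "all" superset column is excluded from testing by
    default; any other column (e.g. a Y-chromosome artifact CIS) can be
    excluded the same way.
    """
    excluded = set(exclude_columns)
    phenos = [c for c in matrix.phenotype_columns if c not in excluded]
    cises = [c for c in matrix.cis_columns if c not in excluded]
    return {
        "pheno_cis": _test_family(matrix, list(product(phenos, cises)), alternative),
        "co_cis": _test_family(matrix, list(combinations(cises, 2)), alternative),
        "pheno_pheno": _test_family(matrix, list(combinations(phenos, 2)), alternative),
    }


def associations_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"item_a": r.item_a, "item_b": r.item_b,
          "n_both": r.table[0], "n_a_only": r.table[1],
          "n_b_only": r.table[2], "n_neither": r.table[3],
          "direction": r.odds_direction,
          "p_raw": r.p_raw, "p_bonferroni": r.p_bonferroni,
          "p_bh": r.p_bh, "n_tests": r.n_tests}
         for r in results],
        columns=["item_a", "item_b", "n_both", "n_a_only", "n_b_only",
                 "n_neither", "direction", "p_raw", "p_bonferroni",
                 "p_bh", "n_tests"],
    )
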