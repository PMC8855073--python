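"""Gene-set over-representation by one-sided Fisher exact test.

Gene sets come from user-supplied GMT collections. Before testing, gene
lists can be filtered by name rules — by default RIKEN identifiers (the
poorly annotated mouse genes with a ``...Rik`` suffix) and any explicitly
excluded genes such as the knockout targets themselves, which would otherwise
dominate the very comparisons that deleted them.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from gseapy.parser import read_gmt as _read_gmt
from scipy import stats

from .de import bh_fdr

logger = logging.getLogger(__name__)

#: fullmatch pattern for RIKEN cDNA gene identifiers
RIKEN_RULE = r".*Rik"


def read_gmt(path: str | Path) -> dict:
    """Read a GMT gene-set collection into {set name: [gene, ...]}."""
    sets = _read_gmt(str(path))
    if len(sets) != len(set(sets)):
        raise ValueError("duplicate set names in GMT")
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def filter_genes(genes: Iterable[str], rules: Sequence[str] = (RIKEN_RULE,)) -> list:
    """Drop genes whose name fully matches any rule (case-sensitive regex).

    The default rule removes RIKEN genes; knockout-target names are passed as
    exact-name rules. Order is preserved.
    """
    pats = [re.compile(r) for r in rules]
    out = [g for g in genes if not any(p.fullmatch(str(g)) for p in pats)]
    if genes and not out:
        logger.warning("gene filter removed every gene")
    return out


def fisher_enrichment(
    query: Iterable[str],
    universe: Iterable[str],
    sets: Mapping[str, Sequence[str]],
    direction_labels: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """One-sided over-representation of the query in each gene set.

    For each set intersected with the universe (empty sets skipped), the
    p-value is the hypergeometric upper tail P(X >= k) with population N =
    |universe|, K = |set ∩ universe| successes and n = |query| draws; BH
    adjustment is across all tested sets and rows are sorted by p. Optional
    ``direction_labels`` (gene -> "up"/"down") yield per-set overlap splits.
    """
    query = set(query)
    universe = set(universe)
    offenders = sorted(query - universe)
    if offenders:
        raise ValueError(f"query genes not in universe: {offenders[:10]}")
    n = len(query)
    N = len(universe)
    rows = []
    for name, members in sets.items():
        in_univ = set(members) & universe
        K = len(in_univ)
        if K == 0:
            continue
        overlap = in_univ & query
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        n_up = n_down = 0
        if direction_labels is not None:
            n_up = sum(1 for g in overlap if direction_labels.get(g) == "up")
            n_down = sum(1 for g in overlap if direction_labels.get(g) == "down")
        rows.append((name, k, K, n, N, p, n_up, n_down))
    out = pd.DataFrame(
        rows, columns=["set", "k", "K", "n", "N", "p", "n_up", "n_down"]
    ).set_index("set")
    if len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
        out = out.sort_values("p", kind="mergesort")
    else:
        out["q"] = pd.Series(dtype=float)
    return out
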