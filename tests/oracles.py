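"""Independent brute-force oracles used to validate the implementations.

Everything here is deliberately naive — exhaustive enumeration, double
loops, closed forms — and shares no code with the package internals.
"""

from __future__ import annotations

import json
import math
import subprocess
import tempfile
from itertools import combinations
from pathlib import Path

import numpy as np


def brute_frequent(transactions, min_support):
    """All itemsets with support >= min_support by full subset enumeration."""
    universe = sorted(set().union(*transactions)) if transactions else []
    n = len(transactions)
    out = {}
    for r in range(1, len(universe) + 1):
        for combo in combinations(universe, r):
            s = frozenset(combo)
            count = sum(1 for t in transactions if s <= t)
            if count / n >= min_support:
                out[s] = count
    return out


def brute_rules(
    transactions,
    min_support,
    min_confidence,
    lift_gt1=False,
    singleton_consequents=True,
    max_len=None,
):
    """All rules meeting the thresholds, enumerated from brute_frequent."""
    n = len(transactions)
    freq = brute_frequent(transactions, min_support)
    rules = set()
    for itemset, count in freq.items():
        if len(itemset) < 2 or (max_len is not None and len(itemset) > max_len):
            continue
        for r in range(1, len(itemset)):
            for cons in combinations(sorted(itemset), r):
                cons = frozenset(cons)
                if singleton_consequents and len(cons) != 1:
                    continue
                ante = itemset - cons
                conf = count / freq[ante]
                if conf < min_confidence:
                    continue
                lift = conf * n / freq[cons]
                if lift_gt1 and not lift > 1:
                    continue
                rules.add(
                    (
                        tuple(sorted(ante)),
                        tuple(sorted(cons)),
                        round(count / n, 12),
                        round(conf, 12),
                        round(lift, 12),
                    )
                )
    return rules


def brute_pair_counts(groups):
    """Co-occurrence counts by double loop over each group's pairs."""
    counts = {}
    for g in groups:
        for a, b in combinations(sorted(g), 2):
            counts[(a, b)] = counts.get((a, b), 0) + 1
    return counts


def phi_closed_form(a, b, c, d):
    """Phi for a 2x2 table with cells (both, x-only, y-only, neither)."""
    denom = math.sqrt((a + b) * (c + d) * (a + c) * (b + d))
    return (a * d - b * c) / denom if denom else 0.0


def brute_jaccard_matrix(sets):
    n = len(sets)
    m = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i != j:
                m[i, j] = len(sets[i] & sets[j]) / len(sets[i] | sets[j])
    return m


def r_hclust_heights(matrices, methods):
    """Merge heights from R's hclust for a batch of distance matrices.

    Returns ``result[matrix_index][method]`` as a list of heights in merge
    order. One Rscript invocation for the whole batch.
    """
    payload = {
        "matrices": [np.asarray(m).tolist() for m in matrices],
        "methods": list(methods),
    }
    with tempfile.TemporaryDirectory() as tmp:
        inp = Path(tmp) / "in.json"
        out = Path(tmp) / "out.json"
        inp.write_text(json.dumps(payload))
        script = Path(tmp) / "hc.R"
        script.write_text(
            """
args <- commandArgs(trailingOnly = TRUE)
payload <- jsonlite::fromJSON(args[1], simplifyMatrix = TRUE)
mats <- payload$matrices
if (is.array(mats) && length(dim(mats)) == 3) {
  mats <- lapply(seq_len(dim(mats)[1]), function(i) mats[i, , ])
}
res <- lapply(mats, function(m) {
  d <- as.dist(as.matrix(m))
  out <- list()
  for (meth in payload$methods) {
    out[[meth]] <- hclust(d, method = meth)$height
  }
  out
})
writeLines(jsonlite::toJSON(res, digits = NA), args[2])
"""
        )
        subprocess.run(
            ["Rscript", str(script), str(inp), str(out)],
            check=True,
            capture_output=True,
            text=True,
        )
        return json.loads(out.read_text())
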