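"""Internal node calculation: roll KO-level values up the Functional Tree.

Every non-KO function receives the sum or the mean of the values of the
*distinct* KO function ids in its subtree — distinct, so that a KO appearing
under several modules of the same pathway is counted once for that pathway.
A function placed under two pathways still contributes its full value to
both parents, so sums are conservative only on trees without
multi-placement.

In mean mode the denominator is, by default, the total number of KOs
assigned under the function (missing KOs count as zero abundance), which is
consistent with how coverage is defined; ``observed_denominator=True``
divides by the number of KOs actually present in the input instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .errors import StatsError
from .hierarchy import FunctionalTree

MODES = ("sum", "mean")


@dataclass(frozen=True)
class ValueMap:
    """Aggregated values keyed by function id."""

    values: Mapping[str, float]
    mode: str


def aggregate_up(tree: FunctionalTree, ko_values: Mapping[str, float],
                 mode: str = "sum", observed_denominator: bool = False,
                 include_root: bool = True) -> ValueMap:
    """Propagate KO values to module/pathway/process/category (and root).

    The hidden Undefined subtree participates: its chain of internal nodes
    receives values like any other (computed, simply never rendered).
    """
    if mode not in MODES:
        raise StatsError("unknown aggregation mode %r (expected sum or mean)" % mode)
    if not ko_values:
        raise StatsError("empty KO value input")
    unknown = sorted(set(ko_values) - set(tree.ko_universe))
    if unknown:
        raise StatsError("unknown KO ids (not in the tree): %s" % ", ".join(unknown))
    bad = sorted(k for k, v in ko_values.items() if not math.isfinite(v))
    if bad:
        raise StatsError("non-finite values for KOs: %s" % ", ".join(bad))

    out: dict[str, float] = {}
    for fid in tree.function_ids(layers=("root", "biological_category",
                                         "biological_process", "pathway", "module"),
                                 include_root=include_root):
        kos = tree.function_ko_set(fid)
        if not kos:
            continue  # function with no assigned KOs has no defined value
        total = sum(ko_values.get(k, 0.0) for k in sorted(kos))
        if mode == "sum":
            out[fid] = total
        else:
            denom = len(kos & set(ko_values)) if observed_denominator else len(kos)
            out[fid] = total / denom if denom else 0.0
    return ValueMap(values=out, mode=mode)
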