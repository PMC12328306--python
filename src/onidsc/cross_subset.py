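"""Cross-subset network comparison: relations shared between subjects.

After inferring one network per subject (or per cell type), edges present
in at least tau subjects form the shared network.  When no single tau is
appropriate, a variable threshold is chosen per cell type so that the
shared network's gene count lands in a target band, making networks of
differently sized cohorts comparable.
"""

from __future__ import annotations

import logging
from collections import Counter

from .io_formats import ValidationError

logger = logging.getLogger(__name__)

__all__ = ["shared_relations", "select_variable_threshold"]


def _support(networks: dict) -> Counter:
    support: Counter = Counter()
    for label, edges in networks.items():
        uniq = set(edges)
        if len(uniq) != len(list(edges)):
            raise ValidationError(f"duplicate edges in subset {label!r}")
        support.update(uniq)
    return support


def shared_relations(networks: dict, tau: int):
    """Edges present in at least ``tau`` of the subset networks.

    ``networks`` maps a label to its set of (regulator, target) pairs.
    Returns (edge set, {edge: support count}).  tau=1 gives the union,
    tau=len(networks) the intersection; the result is monotone decreasing
    in tau and independent of label order.
    """
    if not networks:
        raise ValidationError("no subset networks given")
    if not 1 <= tau <= len(networks):
        raise ValidationError(
            f"tau must be in 1..{len(networks)}, got {tau}"
        )
    support = _support(networks)
    shared = {e for e, c in support.items() if c >= tau}
    return shared, {e: support[e] for e in shared}


def select_variable_threshold(networks: dict, gene_band=(60, 105)):
    """Find the most stringent tau whose shared gene count fits a band.

    Scans tau from len(networks) down to 1 and returns the largest tau for
    which the number of distinct genes (regulators union targets) of the
    shared edge set lies inside ``gene_band``.  If no tau lands in the
    band, the tau whose count is closest to the lower bound from above is
    returned (logged as out-of-band); with no count above the lower bound,
    the tau with the largest count.  Returns (tau, edges, genes).
    """
    low, high = gene_band
    if not 0 < low <= high:
        raise ValidationError(f"invalid gene band {gene_band}")
    results = {}
    for tau in range(len(networks), 0, -1):
        edges, _ = shared_relations(networks, tau)
        genes = {g for e in edges for g in e}
        results[tau] = (edges, genes)
        if low <= len(genes) <= high:
            return tau, edges, genes
    above = {t: r for t, r in results.items() if len(r[1]) >= low}
    if above:
        tau = min(above, key=lambda t: (len(above[t][1]), -t))
        logger.warning(
            "no tau lands in gene band %s; using tau=%d with %d genes",
            gene_band,
            tau,
            len(above[tau][1]),
        )
        return tau, *above[tau]
    best = max(results, key=lambda t: (len(results[t][1]), t))
    if len(results[best][1]) == 0:
        raise ValidationError("shared networks are empty at every threshold")
    logger.warning(
        "all shared gene counts below band %s; using tau=%d with %d genes",
        gene_band,
        best,
        len(results[best][1]),
    )
    return best, *results[best]
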