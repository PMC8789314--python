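"""Precision/recall scoring of called positions against simulation truth."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class RecoveryResult:
    n_true: int
    n_called: int
    n_matched: int
    precision: float | None  # None when undefined (no calls)
    recall: float | None  # None when undefined (empty truth)


def _match_greedy(called, truth, tolerance):
    """One-to-one greedy matching by distance.

    Items are either bare positions or (key..., position) tuples; tuple
    items match only within the same key (contig/strand).
    """

    def split(item):
        if isinstance(item, tuple):
            return item[:-1], item[-1]
        return (), item

    pairs = []
    for i, c in enumerate(called):
        ck, cp = split(c)
        for j, t in enumerate(truth):
            tk, tp = split(t)
            if ck != tk:
                continue
            d = abs(cp - tp)
            if d <= tolerance:
                pairs.append((d, i, j))
    pairs.sort()
    used_c, used_t = set(), set()
    n = 0
    for d, i, j in pairs:
        if i in used_c or j in used_t:
            continue
        used_c.add(i)
        used_t.add(j)
        n += 1
    return n


def evaluate_recovery(called, truth, tolerance=0):
    """Precision and recall of ``called`` against ``truth``.

    Both arguments are lists of positions (or (contig, strand, pos)
    tuples), or dicts category -> list, in which case a dict of per-category
    results is returned.  Matching is one-to-one greedy by distance with
    positional ``tolerance`` (nt).  Empty truth leaves recall undefined
    (``None``); no calls leave precision undefined.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    if isinstance(called, dict) or isinstance(truth, dict):
        called = dict(called) if isinstance(called, dict) else {None: called}
        truth = dict(truth) if isinstance(truth, dict) else {None: truth}
        return {
            cat: evaluate_recovery(called.get(cat, []), truth.get(cat, []), tolerance)
            for cat in sorted(set(called) | set(truth), key=str)
        }
    called = list(called)
    truth = list(truth)
    n = _match_greedy(called, truth, tolerance)
    precision = n / len(called) if called else None
    recall = n / len(truth) if truth else None
    return RecoveryResult(
        n_true=len(truth),
        n_called=len(called),
        n_matched=n,
        precision=precision,
        recall=recall,
    )
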