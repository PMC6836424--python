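"""Independent brute-force oracles, deliberately written without pandas and
without reusing any pumpwatch metrics code, for oracle-equivalence tests."""

from __future__ import annotations

import numpy as np

ALERT_TYPES = ("soft_min", "hard_min", "soft_max", "hard_max")
RESPONSES = ("cancel", "override", "reprogram")


def naive_pairing(records):
    """FIFO alert/response pairing by plain iteration.

    Returns a list of (year, alert_type, drug_name, response-or-None).
    """
    pending: dict[str, list] = {}
    out = []
    for r in records:
        et = getattr(r.event_type, "value", r.event_type)
        if et == "alert":
            item = [
                r.timestamp.year,
                getattr(r.alert_type, "value", r.alert_type),
                r.drug_name,
                None,
            ]
            pending.setdefault(r.infusion_id, []).append(item)
            out.append(item)
        elif et == "response":
            queue = pending.get(r.infusion_id, [])
            for item in queue:
                if item[3] is None:
                    item[3] = getattr(r.response_action, "value", r.response_action)
                    break
    return [tuple(item) for item in out]


def naive_threshold_table(records):
    """Counts by (alert_type, year) and (alert_type, response)."""
    by_type_year: dict[tuple, int] = {}
    by_type_response: dict[tuple, int] = {}
    for year, at, _drug, resp in naive_pairing(records):
        by_type_year[(at, year)] = by_type_year.get((at, year), 0) + 1
        if resp is not None:
            by_type_response[(at, resp)] = by_type_response.get((at, resp), 0) + 1
    return by_type_year, by_type_response


def naive_response_counts(records):
    counts = {r: 0 for r in RESPONSES}
    for _, _, _, resp in naive_pairing(records):
        if resp is not None:
            counts[resp] += 1
    return counts


def naive_alert_frequency(records):
    """(n_starts, n_unique_infusions, n_alerts, n_alerting_infusions), pooled."""
    starts = 0
    start_ids, alert_ids = set(), set()
    alerts = 0
    for r in records:
        et = getattr(r.event_type, "value", r.event_type)
        if et == "infusion_start":
            starts += 1
            start_ids.add(r.infusion_id)
        elif et == "alert":
            alerts += 1
            alert_ids.add(r.infusion_id)
    return starts, len(start_ids), alerts, len(start_ids & alert_ids)


def naive_classify(dose, soft_min, soft_max, hard_min, hard_max):
    """Brute-force limit classification via interval membership.

    Independent formulation: enumerate the five candidate outcomes as
    explicit dose intervals and pick the one containing the dose.
    """
    inf = float("inf")
    # half-open membership: a dose exactly at a hard limit passes the hard
    # check but can still violate the soft limit inside it
    intervals = []
    if hard_max is not None:
        intervals.append(("hard_max", lambda d: d > hard_max))
    top = hard_max if hard_max is not None else inf
    if soft_max is not None:
        intervals.append(("soft_max", lambda d: soft_max < d <= top))
    if hard_min is not None:
        intervals.append(("hard_min", lambda d: d < hard_min))
    bottom = hard_min if hard_min is not None else -inf
    if soft_min is not None:
        intervals.append(("soft_min", lambda d: bottom <= d < soft_min))
    hits = [name for name, member in intervals if member(dose)]
    assert len(hits) <= 1, f"ambiguous classification for dose {dose}: {hits}"
    return hits[0] if hits else "none"


def permutation_trend_pvalue(successes, totals, n_perm=20000, seed=0):
    """Two-sided Monte-Carlo permutation p-value for a trend in proportions.

    Permutes the pooled 0/1 outcomes across the ordered groups and compares
    the score statistic sum_i(score_i * successes_i) against its permutation
    distribution.
    """
    rng = np.random.default_rng(seed)
    successes = np.asarray(successes, dtype=int)
    totals = np.asarray(totals, dtype=int)
    scores = np.arange(len(totals), dtype=float)
    pooled = np.zeros(totals.sum(), dtype=np.int8)
    pooled[: successes.sum()] = 1
    group = np.repeat(scores, totals)
    expected = successes.sum() / totals.sum() * float((scores * totals).sum())
    observed = abs(float((scores * successes).sum()) - expected)
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        stat = abs(float((group * pooled).sum()) - expected)
        if stat >= observed - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)
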