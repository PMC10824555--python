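"""Stimulation-responsive neuron identification and population pre/post tests.

Responses are measured on noise-normalized, onset-centered traces: each
neuron's trial means over the 2 s before and after each stimulation onset are
compared with a paired Wilcoxon signed-rank test; a neuron is responsive when
the (optionally Benjamini-Hochberg adjusted) p-value is below alpha and its
post-stimulation mean exceeds the pre-stimulation mean.  The same paired test
applied to per-trial region-mean fluorescence gives the population-level
result.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import EventTable, TraceMatrix
from .preprocess import center_on_events

__all__ = [
    "population_prepost_test", "identify_responsive", "responsive_by_attribute",
]


def _check_windows(events: EventTable, window: float) -> None:
    gaps = np.diff(events.onset_times)
    if gaps.size and gaps.min() < 2 * window:
        raise ValueError("overlapping windows: analysis window exceeds the "
                         "smallest inter-stimulation gap")


def _paired_wilcoxon(pre: np.ndarray, post: np.ndarray) -> tuple[float, float]:
    diff = post - pre
    if np.allclose(diff, 0):
        return 0.0, 1.0
    res = stats.wilcoxon(post, pre)
    return float(res.statistic), float(res.pvalue)


def population_prepost_test(traces: TraceMatrix, events: EventTable,
                            window: float = 2.0) -> pd.DataFrame:
    """Paired Wilcoxon signed-rank test of per-trial mean fluorescence in the
    `window` seconds before vs after stimulation onset, per region and pooled.

    Trial means are taken over [onset-window, onset) and [onset, onset+window)
    of the region-mean fluorescence.  Needs at least 2 usable trials.
    """
    _check_windows(events, window)
    fs = traces.sampling_rate
    half = int(round(window * fs))
    frames = np.round((events.onset_times - traces.t0) * fs).astype(int)
    frames = frames[(frames - half >= 0) & (frames + half <= traces.n_frames)]
    if len(frames) < 2:
        raise ValueError("need at least 2 stimulation trials inside the recording")
    groups = {"all": np.arange(traces.n_neurons)}
    for region in pd.unique(traces.region_labels):
        groups[str(region)] = np.nonzero(traces.region_labels == region)[0]
    rows = []
    for name, idx in groups.items():
        mean_f = traces.values[idx].mean(axis=0)
        pre = np.array([mean_f[f - half: f].mean() for f in frames])
        post = np.array([mean_f[f: f + half].mean() for f in frames])
        stat, p = _paired_wilcoxon(pre, post)
        rows.append({"region": name, "n_trials": len(frames),
                     "pre_mean": float(pre.mean()), "post_mean": float(post.mean()),
                     "statistic": stat, "p_value": p})
    return pd.DataFrame(rows)


def identify_responsive(traces: TraceMatrix, events: EventTable,
                        window: float = 2.0, alpha: float = 0.05,
                        bh_correction: bool = True) -> pd.DataFrame:
    """Per-neuron stimulation-response test on noise-normalized traces.

    For each neuron, per-trial means over the `window` seconds before and
    after onset (onset-centered snippets) enter a paired Wilcoxon signed-rank
    test; responsive iff (adjusted) p < alpha AND post-mean > pre-mean.
    Returns one row per neuron with pre, post, effect, p, q, is_responsive.
    """
    _check_windows(events, window)
    centered = center_on_events(traces, events, window)
    snips = centered["snippets"]                  # (n_neurons, n_trials, 2*half)
    if snips.shape[1] < 2:
        raise ValueError("need at least 2 stimulation trials inside the recording")
    half = snips.shape[2] // 2
    pre = snips[:, :, :half].mean(axis=2)         # (n_neurons, n_trials)
    post = snips[:, :, half:].mean(axis=2)
    stats_p = np.array([_paired_wilcoxon(pre[i], post[i])
                        for i in range(traces.n_neurons)])
    pvals = stats_p[:, 1]
    if bh_correction:
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    else:
        qvals = pvals
    effect = post.mean(axis=1) - pre.mean(axis=1)
    responsive = (qvals < alpha) & (effect > 0)
    return pd.DataFrame({
        "neuron_id": traces.neuron_ids,
        "region": traces.region_labels,
        "pre_mean": pre.mean(axis=1),
        "post_mean": post.mean(axis=1),
        "effect": effect,
        "p_value": pvals,
        "q_value": qvals,
        "is_responsive": responsive,
    })


def responsive_by_attribute(traces: TraceMatrix, events: EventTable,
                            attribute: str, window: float = 2.0,
                            alpha: float = 0.05,
                            bh_correction: bool = True) -> dict:
    """Split events by an attribute (e.g. stimulation side), identify
    responsive neurons per split, and tabulate the overlap."""
    if events.attributes is None or attribute not in events.attributes:
        raise KeyError(f"event attribute {attribute!r} missing")
    values = pd.unique(events.attributes[attribute])
    per_value: dict = {}
    sets: dict = {}
    for v in values:
        sub = events.select(attribute, v)
        table = identify_responsive(traces, sub, window, alpha, bh_correction)
        per_value[v] = table
        sets[v] = set(np.asarray(table.loc[table.is_responsive, "neuron_id"]).tolist())
    overlap = pd.DataFrame(
        [[len(sets[a] & sets[b]) for b in values] for a in values],
        index=values, columns=values)
    return {"tables": per_value, "responsive_sets": sets, "overlap": overlap}
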