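"""Detection and recognition scoring.

Detection follows classical signal-detection bookkeeping: button presses
are matched to target numerals within a response window; targets with a
matched press are hits, unmatched targets misses. Presses not consumed
by any target are then matched against non-target numerals in the
distractor stream the same way, yielding false alarms and correct
rejections. Sensitivity is d' = Phi^-1(hit rate) - Phi^-1(FA rate),
with extreme rates pulled in by the standard 1/(2N) correction.

The response window is not fixed a priori: latencies pooled over all
participants and conditions are trimmed to their empirical 5–95%
quantile range, which removes presses too fast or too slow to be
genuine target responses.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm

from .datatypes import BehavioralSummary, ResponseLog

#: initial collection window in ms
COLLECTION_WINDOW = (0.0, 2000.0)


def pooled_latencies(logs: "list[ResponseLog]",
                     window: tuple[float, float] = COLLECTION_WINDOW) -> np.ndarray:
    """Press-minus-nearest-preceding-target latencies pooled over logs.

    Only presses falling within the raw collection window of some
    target are counted, one latency per press.
    """
    out = []
    for log in logs:
        for press in log.presses:
            prior = log.targets[log.targets <= press]
            if len(prior):
                lat = press - prior[-1]
                if window[0] <= lat <= window[1]:
                    out.append(lat)
    return np.asarray(out)


def trim_response_window(
    latencies: np.ndarray,
    lower_q: float = 0.05,
    upper_q: float = 0.95,
) -> tuple[float, float]:
    """Empirical quantile window of pooled latencies.

    Falls back to the full collection window with a warning when fewer
    than 20 responses are pooled.
    """
    lat = np.asarray(latencies, dtype=float)
    if len(lat) < 20:
        warnings.warn(
            f"only {len(lat)} pooled responses; using the full collection window"
        )
        return COLLECTION_WINDOW
    lo, hi = np.quantile(lat, [lower_q, upper_q])
    return float(lo), float(hi)


def _greedy_match(
    presses: np.ndarray, onsets: np.ndarray, window: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Match each press to the earliest unmatched onset whose window
    contains it. Returns (matched mask over onsets, consumed mask over
    presses, press-minus-onset latencies of the matches)."""
    lo, hi = window
    matched = np.zeros(len(onsets), dtype=bool)
    consumed = np.zeros(len(presses), dtype=bool)
    latencies: list[float] = []
    next_free = 0
    for pi, press in enumerate(presses):
        for oi in range(next_free, len(onsets)):
            if matched[oi]:
                continue
            if onsets[oi] + lo <= press <= onsets[oi] + hi:
                matched[oi] = True
                consumed[pi] = True
                latencies.append(float(press - onsets[oi]))
                while next_free < len(onsets) and matched[next_free]:
                    next_free += 1
                break
            if onsets[oi] + lo > press:
                break
    return matched, consumed, latencies


def classify_responses(
    log: ResponseLog, window: tuple[float, float]
) -> dict[str, "int | np.ndarray"]:
    """Hit/miss/FA/CR counts for one participant x condition cell.

    A press consumes at most one target (earliest unmatched first);
    presses left over are matched against non-target numerals with the
    same window. Also returns the hit latencies.
    """
    lo, hi = window
    if not lo <= hi:
        raise ValueError("invalid response window")
    t_matched, consumed, hit_rts = _greedy_match(log.presses, log.targets, window)
    leftover = log.presses[~consumed]
    nt_matched, _, _ = _greedy_match(leftover, log.nontargets, window)
    counts = {
        "hits": int(t_matched.sum()),
        "misses": int(len(log.targets) - t_matched.sum()),
        "false_alarms": int(nt_matched.sum()),
        "correct_rejections": int(len(log.nontargets) - nt_matched.sum()),
        "hit_rts_ms": np.asarray(hit_rts),
    }
    assert counts["hits"] + counts["misses"] == len(log.targets)
    assert counts["false_alarms"] + counts["correct_rejections"] == len(log.nontargets)
    return counts


def d_prime(hits: int, misses: int, false_alarms: int, correct_rejections: int) -> float:
    """Phi^-1(hit rate) - Phi^-1(FA rate), rates 0 and 1 replaced by
    1/(2N) and 1 - 1/(2N)."""
    n_t = hits + misses
    n_nt = false_alarms + correct_rejections
    if min(hits, misses, false_alarms, correct_rejections) < 0:
        raise ValueError("negative counts")
    if n_t == 0 or n_nt == 0:
        raise ValueError("need at least one target and one non-target trial")
    hr = np.clip(hits / n_t, 1 / (2 * n_t), 1 - 1 / (2 * n_t))
    fr = np.clip(false_alarms / n_nt, 1 / (2 * n_nt), 1 - 1 / (2 * n_nt))
    return float(norm.ppf(hr) - norm.ppf(fr))


def score_logs(
    logs: "list[ResponseLog]",
    window: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Full scoring pipeline over per-cell response logs.

    When ``window`` is None it is derived by 5–95% trimming of the
    latencies pooled across all logs, as a single window applied to
    every participant and condition.
    """
    if window is None:
        window = trim_response_window(pooled_latencies(logs))
    rows = []
    for log in logs:
        c = classify_responses(log, window)
        dp = d_prime(c["hits"], c["misses"], c["false_alarms"], c["correct_rejections"])
        rows.append(
            BehavioralSummary(
                participant=log.participant, condition=log.condition,
                window_ms=window, hits=c["hits"], misses=c["misses"],
                false_alarms=c["false_alarms"],
                correct_rejections=c["correct_rejections"],
                d_prime=dp, hit_rts_ms=c["hit_rts_ms"],
            )
        )
    return pd.DataFrame(
        {
            "participant": [r.participant for r in rows],
            "condition": [r.condition for r in rows],
            "hits": [r.hits for r in rows],
            "misses": [r.misses for r in rows],
            "false_alarms": [r.false_alarms for r in rows],
            "correct_rejections": [r.correct_rejections for r in rows],
            "hit_rate": [r.hits / max(r.n_targets, 1) for r in rows],
            "fa_rate": [r.false_alarms / max(r.n_nontargets, 1) for r in rows],
            "d_prime": [r.d_prime for r in rows],
            "mean_log_rt": [
                float(np.mean(r.log_rt)) if len(r.hit_rts_ms) else np.nan for r in rows
            ],
            "window_low_ms": window[0],
            "window_high_ms": window[1],
        }
    )


def recognition_index(
    answers: pd.DataFrame,
    high_cut: float = 0.95,
    low_cut: float = 0.30,
    other_source_label: str = "other_source",
) -> pd.DataFrame:
    """Percent correct per participant x condition with item exclusion.

    ``answers`` columns: participant, condition, item, correct (bool),
    confidence. Items whose pooled (all participants and conditions)
    correct rate is above ``high_cut`` or below ``low_cut`` are dropped,
    as are individual answers judged known from another source. Cells
    whose item pool empties return NaN with ``undefined=True``.
    """
    req = {"participant", "condition", "item", "correct"}
    if not req <= set(answers.columns):
        raise ValueError(f"answers table needs columns {sorted(req)}")
    df = answers.copy()
    item_rates = df.groupby("item")["correct"].mean()
    bad_items = set(item_rates[(item_rates > high_cut) | (item_rates < low_cut)].index)
    df = df[~df["item"].isin(bad_items)]
    if "confidence" in df.columns:
        df = df[df["confidence"] != other_source_label]
    cells = answers[["participant", "condition"]].drop_duplicates()
    scored = (
        df.groupby(["participant", "condition"])["correct"]
        .mean()
        .mul(100.0)
        .rename("recognition_index")
        .reset_index()
    )
    out = cells.merge(scored, on=["participant", "condition"], how="left")
    out["undefined"] = out["recognition_index"].isna()
    return out.sort_values(["participant", "condition"]).reset_index(drop=True)
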