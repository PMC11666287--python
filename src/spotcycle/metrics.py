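"""Deconvolution accuracy metrics and the repeated-run protocol.

RMSE is the root mean squared difference over all (spot, type) entries, or
over one type column (``scope="per_type"``). JSD is the per-spot
Jensen–Shannon divergence, base 2 by default so each spot's value lies in
[0, 1], averaged over spots. Benchmarks are summarized over seeded repeats.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["rmse", "jsd", "evaluate_repeated"]


def _as_table(t) -> np.ndarray:
    if isinstance(t, pd.DataFrame):
        t = t.to_numpy()
    return np.asarray(t, dtype=np.float64)


def rmse(truth, pred, scope: str = "overall"):
    """Root mean squared error between two proportion tables.

    ``scope="overall"`` returns a scalar over all entries;
    ``scope="per_type"`` returns one value per type column.
    """
    truth, pred = _as_table(truth), _as_table(pred)
    if truth.shape != pred.shape:
        raise ValueError(f"shape mismatch: {truth.shape} vs {pred.shape}")
    sq = (truth - pred) ** 2
    if scope == "overall":
        return float(np.sqrt(sq.mean()))
    if scope == "per_type":
        return np.sqrt(sq.mean(axis=0))
    raise ValueError(f"unknown scope {scope!r}")


def _kl(p: np.ndarray, q: np.ndarray, log) -> np.ndarray:
    # 0·log 0 = 0 convention; q > 0 wherever p > 0 since q is the mixture
    ratio = np.divide(p, q, out=np.ones_like(p), where=p > 0)
    return np.where(p > 0, p * log(ratio), 0.0).sum(axis=1)


def jsd(truth, pred, base: float = 2.0) -> float:
    """Mean per-spot Jensen–Shannon divergence (base 2 ⇒ bounded [0, 1])."""
    truth, pred = _as_table(truth), _as_table(pred)
    if truth.shape != pred.shape:
        raise ValueError(f"shape mismatch: {truth.shape} vs {pred.shape}")
    for name, t in (("truth", truth), ("pred", pred)):
        if not np.allclose(t.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"{name} rows must sum to 1")
        if (t < 0).any():
            raise ValueError(f"{name} has negative entries")
    log = (lambda x: np.log(x) / np.log(base))
    m = 0.5 * (truth + pred)
    per_spot = 0.5 * _kl(truth, m, log) + 0.5 * _kl(pred, m, log)
    return float(per_spot.mean())


def evaluate_repeated(run, n_repeats: int = 10, seeds=None):
    """Run a seeded experiment repeatedly and summarize RMSE / JSD.

    ``run(seed)`` must return ``(rmse, jsd)``. Failures are recorded per
    repeat; the summary is computed over the successful ones.

    Returns ``(per_repeat_table, summary_dict)``.
    """
    if seeds is None:
        seeds = list(range(n_repeats))
    seeds = list(seeds)[:n_repeats] if n_repeats is not None else list(seeds)
    rows = []
    for rep, seed in enumerate(seeds):
        try:
            r, j = run(seed)
            rows.append({"repeat": rep, "seed": seed, "rmse": float(r),
                         "jsd": float(j), "error": ""})
        except Exception as exc:  # noqa: BLE001 - repeat failures are data
            rows.append({"repeat": rep, "seed": seed, "rmse": np.nan,
                         "jsd": np.nan, "error": str(exc)})
    table = pd.DataFrame(rows, columns=["repeat", "seed", "rmse", "jsd", "error"])
    ok = table[table["error"] == ""]
    summary = {
        "n_requested": len(seeds),
        "n_success": int(len(ok)),
        "rmse_mean": float(ok["rmse"].mean()) if len(ok) else np.nan,
        "rmse_std": float(ok["rmse"].std(ddof=1)) if len(ok) > 1 else 0.0,
        "jsd_mean": float(ok["jsd"].mean()) if len(ok) else np.nan,
        "jsd_std": float(ok["jsd"].std(ddof=1)) if len(ok) > 1 else 0.0,
    }
    return table, summary
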