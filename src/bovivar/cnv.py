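"""Two-sample read-depth CNVR calling.

The model: best-hit read starts of a test and a reference sample are
counted in half-overlapping windows tiling each chromosome. Per window
the copy-number signal is the total-count-normalized ratio

    r = (x / y) * (N_ref / N_test),        log2 ratio = log2(r)

with x, y the test/reference window counts and N the genome-wide
totals. Under the null of equal underlying rates both counts are
Poisson with window means lambda_t, lambda_r proportional to the
totals. Two p-value routes are provided:

``exact-midp`` (default)
    the conditional test: given n = x + y, x ~ Binomial(n, theta0) with
    theta0 = lambda_t / (lambda_t + lambda_r); two-sided mid-p
    (2*min(tails) minus half the probability of the observed count).
    The mid-p correction removes the conservativeness the discrete
    atoms otherwise cause in the extreme tail, so the realized
    false-positive rate matches the nominal threshold.

``gh``
    the Gaussian approximation for the ratio of two independent Poisson
    counts (Geary-Hinkley transformation) with the null window means as
    parameters: z = (lambda_r*T - lambda_t) / sqrt(lambda_t + T^2*lambda_r),
    T = x/y. Slightly conservative below p ~ 1e-3 at moderate counts.

A CNVR is a maximal run of at least ``min_windows`` consecutive
windows that each pass both the p-value and |log2| thresholds with a
common sign; runs never cross chromosome boundaries. Gains are
reported relative to the test sample. The X chromosome is processed
like the autosomes, without ploidy correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .layout import GenomeLayout

log = logging.getLogger("bovivar")

GAIN = "gain-in-test"
LOSS = "gain-in-reference"


@dataclass(frozen=True)
class CNVParams:
    p_threshold: float = 0.001
    log2_threshold: float = 0.7
    min_windows: int = 10
    window_multiplier: float = 5.0   # times the minimum detectable window length
    window_length: int | None = None  # explicit override, bp
    method: str = "exact-midp"        # or "gh"

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold < 1) or self.log2_threshold <= 0:
            raise ValueError("thresholds must be positive (p in (0,1))")
        if self.min_windows < 1:
            raise ValueError("min_windows must be >= 1")
        if self.method not in ("exact-midp", "gh"):
            raise ValueError(f"unknown p-value method {self.method!r}")


@dataclass(frozen=True)
class CNVR:
    chrom: str
    start: int        # 0-based half-open span of member windows
    end: int
    direction: str    # GAIN or LOSS
    n_windows: int
    mean_log2: float
    best_p: float

    @property
    def length(self) -> int:
        return self.end - self.start


def min_window_length(total_test: int, total_ref: int, genome_length: int,
                      params: CNVParams = CNVParams()) -> int:
    """Smallest window length at which a true |log2| at the threshold is
    detectable at the p threshold, from the Gaussian ratio statistic; the
    configured multiplier then gives the working window size."""
    if total_test <= 0 or total_ref <= 0:
        raise ValueError("read totals must be positive")
    z = stats.norm.isf(params.p_threshold / 2)
    dt, dr = total_test / genome_length, total_ref / genome_length
    lengths = []
    for rho in (2.0 ** params.log2_threshold, 2.0 ** -params.log2_threshold):
        T = rho * total_test / total_ref  # raw count ratio at the log2 boundary
        lengths.append(z ** 2 * (dt + T ** 2 * dr) / (dr * T - dt) ** 2)
    return int(np.ceil(max(lengths)))


def window_length_for(total_test: int, total_ref: int, genome_length: int,
                      params: CNVParams = CNVParams()) -> int:
    if params.window_length is not None:
        if params.window_length < 2:
            raise ValueError("window length must be >= 2")
        return int(params.window_length)
    w = int(np.ceil(params.window_multiplier *
                    min_window_length(total_test, total_ref, genome_length, params)))
    log.info("derived window length: %d bp", w)
    return w


def make_windows(test_positions: Mapping[str, np.ndarray],
                 ref_positions: Mapping[str, np.ndarray],
                 layout: GenomeLayout, window_length: int) -> pd.DataFrame:
    """Count read starts (1-based positions) in half-overlapping windows.

    Windows start every ``window_length // 2`` bp from coordinate 0 and are
    clipped at the chromosome end, so each read start falls in at most two
    windows. Returns columns chrom/start/end/test/ref (0-based half-open).
    """
    if window_length < 2:
        raise ValueError("window length must be >= 2")
    stride = window_length // 2
    frames = []
    for chrom, clen in zip(layout.names, layout.lengths):
        starts = np.arange(0, clen, stride, dtype=np.int64)
        ends = np.minimum(starts + window_length, clen)
        keep = ends > starts
        starts, ends = starts[keep], ends[keep]
        tp = np.sort(np.asarray(test_positions.get(chrom, ()), dtype=np.int64)) - 1
        rp = np.sort(np.asarray(ref_positions.get(chrom, ()), dtype=np.int64)) - 1
        frames.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": ends,
            "test": np.searchsorted(tp, ends) - np.searchsorted(tp, starts),
            "ref": np.searchsorted(rp, ends) - np.searchsorted(rp, starts),
        }))
    return pd.concat(frames, ignore_index=True)


def window_statistic(test: np.ndarray, ref: np.ndarray,
                     lambda_test: float | np.ndarray, lambda_ref: float | np.ndarray,
                     method: str = "exact-midp") -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized (log2 ratio, p-value, corrected-flag) for window counts.

    ``lambda_test``/``lambda_ref`` are the null window means. The log2
    ratio is normalized by the null means so it is 0 at the null center;
    windows with a zero count get 0.5 added to both counts for the ratio
    (continuity correction) and are flagged.
    """
    x = np.asarray(test, dtype=np.int64)
    y = np.asarray(ref, dtype=np.int64)
    lt = np.broadcast_to(np.asarray(lambda_test, dtype=float), x.shape)
    lr = np.broadcast_to(np.asarray(lambda_ref, dtype=float), x.shape)
    corrected = (x == 0) | (y == 0)
    xc = np.where(corrected, x + 0.5, x)
    yc = np.where(corrected, y + 0.5, y)
    with np.errstate(divide="ignore"):
        log2 = np.log2((xc / yc) * (lr / lt))

    if method == "gh":
        T = xc / yc
        z = (lr * T - lt) / np.sqrt(lt + T ** 2 * lr)
        p = 2.0 * stats.norm.sf(np.abs(z))
    elif method == "exact-midp":
        n = x + y
        theta = lt / (lt + lr)
        lower = stats.binom.cdf(x, n, theta)
        upper = stats.binom.sf(x - 1, n, theta)
        pmf = stats.binom.pmf(x, n, theta)
        p = 2.0 * np.minimum(lower, upper) - pmf
        p = np.where(n == 0, 1.0, p)
    else:
        raise ValueError(f"unknown p-value method {method!r}")
    return log2, np.clip(p, 0.0, 1.0), corrected


def score_windows(windows: pd.DataFrame, total_test: int, total_ref: int,
                  layout: GenomeLayout, params: CNVParams = CNVParams()) -> pd.DataFrame:
    """Attach log2/p columns to a window-count table.

    Null window means are the per-sample genome-wide read-start density
    times the window length (per window, so clipped end windows get the
    proportionally smaller mean).
    """
    if total_test <= 0 or total_ref <= 0:
        raise ValueError("read totals must be positive")
    out = windows.copy()
    wlen = (out["end"] - out["start"]).to_numpy()
    g = layout.total_length
    log2, p, corrected = window_statistic(
        out["test"].to_numpy(), out["ref"].to_numpy(),
        lambda_test=total_test * wlen / g, lambda_ref=total_ref * wlen / g,
        method=params.method)
    out["log2"] = log2
    out["p"] = p
    out["corrected"] = corrected
    return out


def call_cnvrs(scored: pd.DataFrame, params: CNVParams = CNVParams()) -> list[CNVR]:
    """Merge runs of >= ``min_windows`` consecutive significant same-sign
    windows into CNVRs. Windows must be the scored output of
    :func:`score_windows` (sorted by chrom, start)."""
    cnvrs: list[CNVR] = []
    for chrom, sub in scored.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        sig = ((sub["p"] <= params.p_threshold) &
               (sub["log2"].abs() >= params.log2_threshold) &
               np.isfinite(sub["log2"])).to_numpy()
        sign = np.sign(sub["log2"].to_numpy())
        # run label changes whenever significance or sign changes
        state = np.where(sig, sign, 0.0)
        change = np.concatenate([[True], state[1:] != state[:-1]])
        run_id = np.cumsum(change)
        for rid in np.unique(run_id):
            idx = np.flatnonzero(run_id == rid)
            if state[idx[0]] == 0 or len(idx) < params.min_windows:
                continue
            block = sub.iloc[idx]
            cnvrs.append(CNVR(
                chrom=str(chrom),
                start=int(block["start"].iloc[0]),
                end=int(block["end"].iloc[-1]),
                direction=GAIN if state[idx[0]] > 0 else LOSS,
                n_windows=len(idx),
                mean_log2=float(block["log2"].mean()),
                best_p=float(block["p"].min()),
            ))
    cnvrs.sort(key=lambda c: (c.chrom, c.start))
    return cnvrs


def summarize_cnvrs(cnvrs: list[CNVR], layout: GenomeLayout) -> dict:
    """Per-chromosome length summary plus direction tally and genome fraction."""
    cols = ["count", "total_bp", "mean_length", "median_length", "min_length", "max_length"]
    if not cnvrs:
        table = pd.DataFrame(columns=cols)
        return {"per_chromosome": table, "total_count": 0, "total_bp": 0,
                "direction": {GAIN: 0, LOSS: 0}, "genome_fraction": 0.0}
    df = pd.DataFrame([{"chrom": c.chrom, "length": c.length, "direction": c.direction}
                       for c in cnvrs])
    g = df.groupby("chrom")["length"]
    table = pd.DataFrame({
        "count": g.size(), "total_bp": g.sum(), "mean_length": g.mean(),
        "median_length": g.median(), "min_length": g.min(), "max_length": g.max(),
    })
    total_bp = int(df["length"].sum())
    return {
        "per_chromosome": table,
        "total_count": len(df),
        "total_bp": total_bp,
        "direction": df["direction"].value_counts().reindex([GAIN, LOSS], fill_value=0).to_dict(),
        "genome_fraction": total_bp / layout.total_length,
    }


def cnvrs_to_frame(cnvrs: list[CNVR]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": c.chrom, "start": c.start, "end": c.end, "direction": c.direction,
        "n_windows": c.n_windows, "mean_log2": c.mean_log2, "best_p": c.best_p,
    } for c in cnvrs], columns=["chrom", "start", "end", "direction",
                                "n_windows", "mean_log2", "best_p"])
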