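"""Epileptogenic-zone delineation from per-channel HFO rates.

Channels are ranked in descending order of retained-event rate; the putative
EZ is the minimal prefix of the ranking whose cumulative event count reaches
the coverage fraction (default 72%) of all events. Fast ripples are the
primary band; when no fast ripple was retained anywhere, ripple counts are
used instead (the fallback is recorded).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class EZParams:
    coverage: float = 0.72
    band_priority: tuple[str, ...] = ("fast-ripple", "ripple")
    # "events": minimal top-ranked set covering `coverage` of all events
    # (default reading); "channels": top `coverage` fraction of
    # event-positive channels.
    rule: str = "events"

    def __post_init__(self) -> None:
        if not 0 < self.coverage <= 1:
            raise ValueError("coverage must be in (0, 1]")
        if self.rule not in ("events", "channels"):
            raise ValueError("rule must be 'events' or 'channels'")


@dataclass
class ChannelRanking:
    """Channels in descending rate order with cumulative event fractions."""

    channels: list[str]
    rates: np.ndarray            # descending
    counts: np.ndarray
    cum_fractions: np.ndarray    # non-decreasing; last == 1 if any events


def rank_channels(rates: dict[str, float],
                  counts: dict[str, int] | None = None) -> ChannelRanking:
    """Stable descending sort by rate; ties keep input order.

    ``counts`` default to the rates themselves (with one fixed-duration
    segment, rates and counts are proportional, so cumulative fractions
    agree).
    """
    labels = list(rates)
    vals = np.array([rates[c] for c in labels], dtype=float)
    order = np.argsort(-vals, kind="stable")
    channels = [labels[i] for i in order]
    sorted_rates = vals[order]
    cnt_source = counts if counts is not None else rates
    sorted_counts = np.array([cnt_source[c] for c in channels], dtype=float)
    total = sorted_counts.sum()
    cum = (np.cumsum(sorted_counts) / total if total > 0
           else np.zeros_like(sorted_counts))
    return ChannelRanking(channels=channels, rates=sorted_rates,
                          counts=sorted_counts, cum_fractions=cum)


def delineate_ez(ranking: ChannelRanking,
                 params: EZParams | None = None) -> list[str]:
    """Minimal top-ranked channel prefix covering the target event fraction.

    Channels with zero events are never included. With no events at all an
    empty set is returned with a warning.
    """
    params = params or EZParams()
    total = ranking.counts.sum()
    if total <= 0:
        warnings.warn("no events in any channel; EZ is empty")
        return []
    positive = [i for i, c in enumerate(ranking.counts) if c > 0]
    if params.rule == "channels":
        k = int(np.ceil(params.coverage * len(positive)))
        return [ranking.channels[i] for i in positive[:k]]
    cum = 0.0
    ez: list[str] = []
    for i in positive:
        ez.append(ranking.channels[i])
        cum += ranking.counts[i]
        if cum >= params.coverage * total - 1e-9:
            break
    return ez


def select_band(events: pd.DataFrame,
                params: EZParams | None = None
                ) -> tuple[str | None, dict[str, int]]:
    """Pick the analysis band: fast ripples if any were retained, else
    ripples.

    Returns ``(band_used, per-channel retained counts)``; ``(None, {})``
    with a warning when nothing was retained at all.
    """
    params = params or EZParams()
    retained = events[events["retained"] == True] if not events.empty \
        else events  # noqa: E712
    for band in params.band_priority:
        sub = retained[retained["band"] == band] if not retained.empty \
            else retained
        if not sub.empty:
            counts = sub.groupby("channel").size().to_dict()
            if band != params.band_priority[0]:
                logger.info("no %s retained; falling back to %s",
                            params.band_priority[0], band)
            return band, {str(k): int(v) for k, v in counts.items()}
    warnings.warn("no retained events in any band")
    return None, {}


def ez_report(events: pd.DataFrame, duration_s: float,
              channels: list[str] | None = None,
              params: EZParams | None = None) -> dict:
    """Full EZ delineation report (JSON-ready).

    Combines band selection, ranking, and the coverage rule; each channel
    row carries its rate, cumulative event fraction, and EZ membership.
    """
    from .detector import channel_rates

    params = params or EZParams()
    band, counts = select_band(events, params)
    if band is None:
        return {"band_used": None, "coverage": params.coverage,
                "ez_channels": [], "ranked_channels": []}
    rates_df = channel_rates(events, duration_s, channels)
    band_rates = rates_df[rates_df["band"] == band]
    rates = dict(zip(band_rates["channel"], band_rates["rate_per_min"]))
    full_counts = {c: counts.get(c, 0) for c in rates}
    ranking = rank_channels(rates, full_counts)
    ez = set(delineate_ez(ranking, params))
    return {
        "band_used": band,
        "coverage": params.coverage,
        "ez_channels": sorted(ez),
        "ranked_channels": [
            {"label": c, "rate": float(r), "cum_fraction": float(f),
             "in_ez": c in ez}
            for c, r, f in zip(ranking.channels, ranking.rates,
                               ranking.cum_fractions)],
    }


def write_ez_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1)
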