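"""Database curation filters and summary statistics for strength entries.

Complex entries are kept only when all quantum-chemical stages converged,
the hydrogen-bond X-H distance in the optimized complex does not exceed a
role-specific cutoff (2.40 Angstrom for acceptor complexes, 2.65 for donor
complexes), and the most negative normal mode is not below -50 cm^-1
(strongly imaginary modes indicate incomplete optimizations).

Statistics cover the free-energy and distance distributions (per functional
class or pooled) and the Pearson correlation between hydrogen-bond distance
and complexation free energy, optionally restricted by site element.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .molio import StrengthEntry

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CurationConfig:
    max_xh_hba: float = 2.40  # Angstrom, acceptor complexes
    max_xh_hbd: float = 2.65  # Angstrom, donor complexes
    min_freq: float = -50.0  # cm^-1, most negative allowed normal mode

    def __post_init__(self) -> None:
        if self.max_xh_hba <= 0 or self.max_xh_hbd <= 0:
            raise ValueError("distance cutoffs must be positive")
        if self.min_freq > 0:
            raise ValueError("min_freq must be <= 0")

    def max_xh(self, role: str) -> float:
        return self.max_xh_hba if role == "HBA" else self.max_xh_hbd


def xh_distance(entry: StrengthEntry) -> float | None:
    """The hydrogen-bond X-H distance: stored tag value if present, else
    recomputed from the complex 3D coordinates via the tagged donated-H and
    acceptor atom indices."""
    if entry.xh_distance is not None:
        return entry.xh_distance
    if (
        entry.fragment.coords3d is not None
        and entry.donated_h_index is not None
        and entry.acceptor_index is not None
    ):
        a = np.array(entry.fragment.coords3d[entry.donated_h_index])
        b = np.array(entry.fragment.coords3d[entry.acceptor_index])
        return float(np.linalg.norm(a - b))
    return None


def filter_complex_entry(
    entry: StrengthEntry, cfg: CurationConfig | None = None
) -> tuple[bool, str | None]:
    """(keep, reason): first failing rule in order converged, distance, freq."""
    cfg = cfg or CurationConfig()
    if entry.converged is False:
        return False, "not_converged"
    d = xh_distance(entry)
    if d is not None and d > cfg.max_xh(entry.role):
        return False, "distance"
    if entry.lowest_freq is not None and entry.lowest_freq < cfg.min_freq:
        return False, "frequency"
    return True, None


def curate(
    entries: list[StrengthEntry], cfg: CurationConfig | None = None
) -> tuple[list[StrengthEntry], list[tuple[StrengthEntry, str]]]:
    """Split entries into kept and rejected-with-reason."""
    kept, rejected = [], []
    for entry in entries:
        ok, reason = filter_complex_entry(entry, cfg)
        (kept.append(entry) if ok else rejected.append((entry, reason)))
    return kept, rejected


def database_summary(
    entries: list[StrengthEntry],
    group_by: str = "none",
    dg_bin_width: float = 1.0,
    xh_bin_width: float = 0.05,
) -> pd.DataFrame:
    """Per-group n/mean/sd/min/max of calibrated dG and X-H distance.

    ``group_by`` is ``functional_class`` or ``none`` (single pooled group
    labelled ``total``); empty groups are omitted with a log entry.  Histogram
    bin counts at the configured widths are attached as list-valued columns.
    """
    if group_by not in ("none", "functional_class"):
        raise ValueError(f"unknown group_by {group_by!r}")
    frame = pd.DataFrame(
        {
            "dg": [e.dg_calibrated for e in entries],
            "xh": [xh_distance(e) for e in entries],
            "group": [
                "total" if group_by == "none" else (e.functional_class or "unassigned")
                for e in entries
            ],
        }
    )
    rows = []
    for label, sub in frame.groupby("group", sort=True):
        dg = sub["dg"].dropna()
        if dg.empty:
            logger.info("group %s has no dG values; omitted", label)
            continue
        xh = sub["xh"].dropna()
        row = {
            "group": label,
            "n": len(dg),
            "dg_mean": dg.mean(),
            "dg_sd": dg.std(ddof=1) if len(dg) > 1 else 0.0,
            "dg_min": dg.min(),
            "dg_max": dg.max(),
            "dg_hist": _hist(dg.to_numpy(), dg_bin_width),
            "xh_n": len(xh),
            "xh_mean": xh.mean() if len(xh) else math.nan,
            "xh_sd": xh.std(ddof=1) if len(xh) > 1 else math.nan,
            "xh_min": xh.min() if len(xh) else math.nan,
            "xh_max": xh.max() if len(xh) else math.nan,
            "xh_hist": _hist(xh.to_numpy(), xh_bin_width) if len(xh) else [],
        }
        rows.append(row)
    return pd.DataFrame(rows)


def _hist(values: np.ndarray, width: float) -> list[int]:
    if len(values) == 0:
        return []
    lo = math.floor(values.min() / width) * width
    hi = math.ceil(values.max() / width) * width
    nbins = max(1, round((hi - lo) / width))
    counts, _ = np.histogram(values, bins=nbins, range=(lo, lo + nbins * width))
    return counts.tolist()


def distance_energy_correlation(
    entries: list[StrengthEntry], subset: str = "all"
) -> float:
    """Pearson r between X-H distances and calibrated dG values.

    ``subset`` restricts by site element (``O``, ``N`` or ``all``).  Entries
    without both quantities are excluded; fewer than 3 usable pairs or zero
    variance in either variable is an error.
    """
    xs, ys = [], []
    for entry in entries:
        if subset != "all" and entry.site_element() != subset:
            continue
        d = xh_distance(entry)
        if d is None or entry.dg_calibrated is None:
            continue
        xs.append(d)
        ys.append(entry.dg_calibrated)
    if len(xs) < 3:
        raise ValueError(f"need >= 3 paired observations, got {len(xs)}")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("undefined correlation: zero variance")
    return float(stats.pearsonr(xs, ys).statistic)
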