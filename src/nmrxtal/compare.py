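"""Experiment-vs-calculation scoring: residuals, RMSD, max difference, ranking.

The residual convention is calc - exp throughout; published tables quote
unsigned "discrepancies", so reports print absolute values while signs are
retained internally.  A precision-emulation flag recomputes statistics
from inputs rounded to table precision (1 decimal ppm) to reproduce
numbers derived from printed tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConsistencyError


@dataclass
class ComparisonStats:
    """RMSD, max |residual| with site attribution, and per-site residuals."""

    n: int
    rmsd: float
    max_abs_diff: float
    argmax_site: str
    residuals: dict[str, float]  # site -> calc - exp, ppm
    model_id: str = ""


def compare_shifts(
    exp: Mapping[str, float],
    calc: Mapping[str, float],
    model_id: str = "",
    table_precision: bool = False,
) -> tuple[ComparisonStats, list[str]]:
    """Score a calculated shift column against experiment, paired by site.

    Returns (stats, unpaired site labels).  ``table_precision=True``
    rounds both columns to 1 decimal ppm before differencing, emulating
    statistics computed from printed tables.  Ties in |residual| break to
    the first site in label sort order.
    """
    sites = sorted(set(exp) & set(calc))
    unpaired = sorted(set(exp) ^ set(calc))
    if not sites:
        raise ConsistencyError("no paired sites between experiment and calculation")
    rnd = (lambda x: round(x, 1)) if table_precision else (lambda x: x)
    residuals = {s: rnd(calc[s]) - rnd(exp[s]) for s in sites}
    vals = np.array([residuals[s] for s in sites])
    rmsd = float(np.sqrt(np.mean(vals ** 2)))
    imax = int(np.argmax(np.abs(vals)))
    stats = ComparisonStats(len(sites), rmsd, float(abs(vals[imax])),
                            sites[imax], residuals, model_id)
    return stats, unpaired


def solution_solid_differences(
    solid: Mapping[str, float],
    solution: Mapping[str, float],
) -> tuple[dict[str, float], tuple[str, float]]:
    """Signed solid - solution shift differences plus the max |difference|.

    Rotamer-alternate solution values are the caller's concern: pass the
    primary column only (alternates are stored separately in ShiftTable).
    """
    sites = sorted(set(solid) & set(solution))
    diffs = {s: solid[s] - solution[s] for s in sites}
    if not diffs:
        return diffs, ("", 0.0)
    argmax = max(sites, key=lambda s: abs(diffs[s]))
    return diffs, (argmax, abs(diffs[argmax]))


def rank_models(stats: Iterable[ComparisonStats]) -> pd.DataFrame:
    """Order models by RMSD ascending; flag RMSD/max-diff rank disagreement.

    All models must score the same site set; a mismatch raises with the
    asymmetric difference listed.
    """
    stats = list(stats)
    if len(stats) < 2:
        raise ValueError("ranking needs at least two models")
    ref_sites = set(stats[0].residuals)
    for s in stats[1:]:
        if set(s.residuals) != ref_sites:
            diff = sorted(set(s.residuals) ^ ref_sites)
            raise ConsistencyError(f"site sets differ between models: {diff}")
    df = pd.DataFrame({
        "model": [s.model_id for s in stats],
        "n": [s.n for s in stats],
        "rmsd": [s.rmsd for s in stats],
        "max_abs_diff": [s.max_abs_diff for s in stats],
        "argmax_site": [s.argmax_site for s in stats],
    }).sort_values("rmsd", kind="stable").reset_index(drop=True)
    rank_by_max = df["max_abs_diff"].rank(method="min")
    rank_by_rmsd = df["rmsd"].rank(method="min")
    df["orderings_agree"] = bool((rank_by_max == rank_by_rmsd).all())
    return df


def stats_to_text(stats: ComparisonStats) -> str:
    """Aligned-column report of one comparison."""
    lines = [f"model: {stats.model_id or '(unnamed)'}   n = {stats.n}",
             f"RMSD      {stats.rmsd:8.2f} ppm",
             f"max diff  {stats.max_abs_diff:8.2f} ppm at {stats.argmax_site}",
             "site      calc-exp (ppm)"]
    for s in sorted(stats.residuals):
        lines.append(f"{s:<10}{stats.residuals[s]:8.2f}")
    return "\n".join(lines) + "\n"
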