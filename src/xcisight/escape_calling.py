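"""Flagging variants and genes that escape X inactivation.

A gene expressed from both the active and the inactive X produces bi-allelic
expression despite chromosome-wide skewing.  A phased heterozygous variant is
an escape candidate when its allelic ratio lies more than two standard
deviations from its phase group's chromosome-wide mean AND shows bi-allelic
expression (ratio between 0.1 and 0.9).  Candidates below the minimum depth
(default 7X) are downgraded to low-confidence rather than dropped, mirroring
post-hoc false-positive labeling; everything else is subject to XCI.

The mean and SD are the empirical summaries of the phase group's ratios by
default (``use_beta_sd`` switches to the fitted beta dispersion).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import AllelicObservation, Phase


class EscapeVerdict(str, Enum):
    ESCAPE_CANDIDATE = "escape_candidate"
    SUBJECT = "subject"
    LOW_CONFIDENCE = "low_confidence"


@dataclass
class EscapeCall:
    observation: AllelicObservation
    gene: Optional[str]
    phased_mean: float
    phased_sd: float
    z_distance: float
    biallelic: bool
    low_coverage_fp: bool
    verdict: EscapeVerdict


@dataclass
class PhaseGroupStats:
    mean: float
    sd: float
    n: int


def phase_group_stats(
    observations: Sequence[AllelicObservation],
) -> dict[Phase, PhaseGroupStats]:
    """Empirical mean/SD of the allelic ratios per phase group."""
    out = {}
    for phase in (Phase.MATERNAL, Phase.PATERNAL):
        ratios = np.array([o.ratio for o in observations if o.phase is phase])
        if len(ratios) >= 2:
            out[phase] = PhaseGroupStats(
                mean=float(ratios.mean()), sd=float(ratios.std(ddof=1)), n=len(ratios)
            )
    return out


def classify_escape(
    obs: AllelicObservation,
    phased_mean: float,
    phased_sd: float,
    min_depth: int = 7,
    biallelic_bounds: tuple[float, float] = (0.1, 0.9),
) -> EscapeCall:
    """Classify one phased observation against its phase group distribution."""
    if obs.phase is Phase.UNPHASED:
        raise ValueError(f"observation at {obs.chrom}:{obs.pos} is unphased")
    if phased_sd <= 0:
        raise ValueError("phased_sd must be positive")
    z = abs(obs.ratio - phased_mean) / phased_sd
    lo, hi = biallelic_bounds
    biallelic = lo <= obs.ratio <= hi
    outlier = z > 2.0
    low_cov = obs.depth < min_depth
    if outlier and biallelic:
        verdict = EscapeVerdict.LOW_CONFIDENCE if low_cov else EscapeVerdict.ESCAPE_CANDIDATE
    else:
        verdict = EscapeVerdict.SUBJECT
    return EscapeCall(
        observation=obs,
        gene=obs.gene,
        phased_mean=phased_mean,
        phased_sd=phased_sd,
        z_distance=float(z),
        biallelic=biallelic,
        low_coverage_fp=bool(outlier and biallelic and low_cov),
        verdict=verdict,
    )


def call_escape(
    observations: Sequence[AllelicObservation],
    min_depth: int = 7,
    stats: Optional[dict[Phase, PhaseGroupStats]] = None,
) -> list[EscapeCall]:
    """Classify every phased observation against its own phase group."""
    stats = stats or phase_group_stats(observations)
    calls = []
    for obs in observations:
        if obs.phase is Phase.UNPHASED or obs.phase not in stats:
            continue
        group = stats[obs.phase]
        calls.append(
            classify_escape(obs, group.mean, group.sd, min_depth=min_depth)
        )
    return calls


def escape_summary(calls: Sequence[EscapeCall]) -> pd.DataFrame:
    """Per-gene roll-up: a gene is a candidate if any of its variants is.

    Returns columns (gene, n_variants, n_candidates, n_low_confidence,
    verdict); variants without a gene label are grouped under ''.
    """
    rows: dict[str, dict] = {}
    for call in calls:
        gene = call.gene or ""
        row = rows.setdefault(
            gene, {"gene": gene, "n_variants": 0, "n_candidates": 0, "n_low_confidence": 0}
        )
        row["n_variants"] += 1
        if call.verdict is EscapeVerdict.ESCAPE_CANDIDATE:
            row["n_candidates"] += 1
        elif call.verdict is EscapeVerdict.LOW_CONFIDENCE:
            row["n_low_confidence"] += 1
    for row in rows.values():
        if row["n_candidates"] > 0:
            row["verdict"] = EscapeVerdict.ESCAPE_CANDIDATE.value
        elif row["n_low_confidence"] > 0:
            row["verdict"] = EscapeVerdict.LOW_CONFIDENCE.value
        else:
            row["verdict"] = EscapeVerdict.SUBJECT.value
    return pd.DataFrame(sorted(rows.values(), key=lambda r: r["gene"]))
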