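"""Deterministic transformations applied before model fitting.

Lipid correction of d13C from the C:N ratio, standardization of fish lengths
(within-species centering, one common scale), trophic-enrichment lookups,
pooling of isotopically overlapping sources, and summarization of raw source
samples into the mean/SD/n form the mixing model consumes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io import ConsumerRecord, SourceSample, SourceSummary, TEFSpec

__all__ = [
    "PreprocessReport",
    "lipid_correct",
    "lipid_correct_records",
    "standardize_lengths",
    "tef_for",
    "pool_sources",
    "summarize_sources",
    "source_overlap",
]

#: C:N ratio above which muscle tissue is considered lipid-rich.
LIPID_CN_THRESHOLD = 3.5


@dataclass
class PreprocessReport:
    """What the preprocessing stage did, for the run manifest."""

    n_lipid_corrected: int = 0
    length_center: dict[str, float] = field(default_factory=dict)  # per species, mm
    length_scale: float = float("nan")  # common SD, mm
    pooled_sources: list[tuple[tuple[str, ...], str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_lipid_corrected": self.n_lipid_corrected,
            "length_center_mm": self.length_center,
            "length_scale_mm": self.length_scale,
            "pooled_sources": [
                {"members": list(members), "pooled_name": name}
                for members, name in self.pooled_sources
            ],
        }


def lipid_correct(
    d13C: float, cn_ratio: float, threshold: float = LIPID_CN_THRESHOLD
) -> tuple[float, bool]:
    """Correct a muscle d13C value for lipid content from its C:N ratio.

    Lipids are depleted in 13C, biasing bulk-tissue d13C low in fatty
    tissue.  For C:N above the threshold the corrected value is
    ``d13C + 6 - 22.2 / cn_ratio``; at or below the threshold the value is
    returned unchanged.  Returns ``(corrected_value, applied_flag)``.
    """
    if not (cn_ratio > 0):
        raise ValueError("cn_ratio must be > 0")
    if cn_ratio > threshold:
        return d13C + 6.0 - 22.2 / cn_ratio, True
    return d13C, False


def lipid_correct_records(
    records: Sequence[ConsumerRecord], threshold: float = LIPID_CN_THRESHOLD
) -> tuple[list[ConsumerRecord], int]:
    """Apply lipid correction to every record with a C:N ratio.

    Records without a C:N ratio pass through untouched.  Corrected records
    are flagged ``lipid_corrected=True``; the count of corrections is
    returned alongside.
    """
    out: list[ConsumerRecord] = []
    n_corrected = 0
    for r in records:
        if r.cn_ratio is None or r.lipid_corrected:
            out.append(r)
            continue
        corrected, applied = lipid_correct(r.d13C, r.cn_ratio, threshold)
        if applied:
            out.append(replace(r, d13C=corrected, lipid_corrected=True))
            n_corrected += 1
        else:
            out.append(r)
    return out, n_corrected


def standardize_lengths(
    records: Sequence[ConsumerRecord],
) -> tuple[np.ndarray, PreprocessReport]:
    """Standardize fish lengths: center within species, scale by a common SD.

    Centering each species on its own mean length encodes the assumption that
    length shifts diet within a species, not between species; dividing by one
    pooled within-species SD keeps the length coefficient comparable (and
    shareable) across species.  Returns the z-scores in record order and a
    report with the centers and the common scale.
    """
    if len(records) < 2:
        raise ValueError("need >= 2 records to standardize lengths")
    lengths = np.array([r.standard_length for r in records], dtype=float)
    species = np.array([r.species_code for r in records])

    centers: dict[str, float] = {}
    centered = np.empty_like(lengths)
    ss = 0.0  # pooled within-species sum of squares
    dof = 0
    for sp in dict.fromkeys(species):  # stable order
        mask = species == sp
        mu = float(lengths[mask].mean())
        centers[sp] = mu
        centered[mask] = lengths[mask] - mu
        k = int(mask.sum())
        if k > 1:
            ss += float(((lengths[mask] - mu) ** 2).sum())
            dof += k - 1
    if dof == 0 or ss == 0.0:
        raise ValueError(
            "length scale undefined: no within-species length variation"
        )
    scale = math.sqrt(ss / dof)
    report = PreprocessReport(length_center=centers, length_scale=scale)
    return centered / scale, report


def tef_for(guild: str, tracer: str, tef_table: Sequence[TEFSpec]) -> tuple[float, float]:
    """Exact lookup of the (mean, sd) trophic enrichment for guild x tracer."""
    for spec in tef_table:
        if spec.guild == guild:
            if tracer not in spec.means:
                raise KeyError(f"TEF entry for guild {guild!r} lacks tracer {tracer!r}")
            return spec.means[tracer], spec.sds[tracer]
    raise KeyError(f"no TEF entry for guild {guild!r}")


def pool_sources(
    a: Sequence[SourceSample],
    b: Sequence[SourceSample],
    pooled_name: str,
) -> list[SourceSample]:
    """Concatenate the raw samples of two sources under one pooled name.

    Used when two basal sources overlap so much in iso-space that the mixing
    model cannot separate them (e.g. leaf litter and fine seston).  Pooling
    concatenates raw samples, so the downstream summary is the combined
    mean/SD with the combined n.
    """
    if not a or not b:
        raise ValueError("both source collections must be non-empty")
    tr_a = {s.tracers for s in a}
    tr_b = {s.tracers for s in b}
    if len(tr_a | tr_b) != 1:
        raise ValueError(
            f"cannot pool sources with different tracer sets: {tr_a} vs {tr_b}"
        )
    return [
        replace(s, source_name=pooled_name) for s in list(a) + list(b)
    ]


def summarize_sources(samples: Sequence[SourceSample]) -> list[SourceSummary]:
    """Collapse raw source samples into per-source per-tracer mean/SD/n.

    SDs use the n-1 denominator.  A source with a single sample has no
    defined SD and is an error; a source whose samples are identical gets
    SD 0 with a degeneracy warning.
    """
    if not samples:
        raise ValueError("no source samples to summarize")
    order = list(dict.fromkeys(s.source_name for s in samples))
    out: list[SourceSummary] = []
    for name in order:
        group = [s for s in samples if s.source_name == name]
        if len(group) < 2:
            raise ValueError(
                f"source {name!r} has n={len(group)}; need >= 2 samples for an SD"
            )
        means: dict[str, float] = {}
        sds: dict[str, float] = {}
        for tracer in ("d13C", "d15N"):
            vals = [getattr(s, tracer) for s in group if getattr(s, tracer) is not None]
            if not vals:
                continue
            if len(vals) != len(group):
                raise ValueError(
                    f"source {name!r}: tracer {tracer} present in only "
                    f"{len(vals)}/{len(group)} samples"
                )
            arr = np.asarray(vals, dtype=float)
            means[tracer] = float(arr.mean())
            sds[tracer] = float(arr.std(ddof=1))
            if sds[tracer] == 0.0:
                warnings.warn(
                    f"source {name!r} tracer {tracer}: all samples identical, SD 0",
                    stacklevel=2,
                )
        out.append(SourceSummary(source_name=name, means=means, sds=sds, n=len(group)))
    return out


def source_overlap(
    a: SourceSummary,
    b: SourceSummary,
    tracers: Sequence[str] = ("d13C", "d15N"),
    threshold: float = 0.8,
    grid_points: int = 101,
    grid_sds: float = 4.0,
) -> tuple[float, bool]:
    """Score how much two sources overlap in iso-space, in [-1, 1].

    The score is the Pearson correlation of the two sources' implied normal
    densities (independent marginals per tracer) evaluated on a shared grid
    spanning both sources.  It is 1 for identical summaries and ~0 for
    well-separated ones.  The returned flag marks score > threshold; the
    decision to pool remains with the analyst.
    """
    for t in tracers:
        if t not in a.means or t not in b.means:
            raise ValueError(f"both sources must carry tracer {t!r}")

    dens_a = np.ones(1)
    dens_b = np.ones(1)
    for t in tracers:
        mu_a, sd_a = a.means[t], max(a.sds[t], 1e-9)
        mu_b, sd_b = b.means[t], max(b.sds[t], 1e-9)
        lo = min(mu_a - grid_sds * sd_a, mu_b - grid_sds * sd_b)
        hi = max(mu_a + grid_sds * sd_a, mu_b + grid_sds * sd_b)
        grid = np.linspace(lo, hi, grid_points)
        da = np.exp(-0.5 * ((grid - mu_a) / sd_a) ** 2) / sd_a
        db = np.exp(-0.5 * ((grid - mu_b) / sd_b) ** 2) / sd_b
        dens_a = np.outer(dens_a, da).ravel()
        dens_b = np.outer(dens_b, db).ravel()

    da = dens_a - dens_a.mean()
    db = dens_b - dens_b.mean()
    denom = math.sqrt(float(da @ da) * float(db @ db))
    score = float(da @ db) / denom if denom > 0 else 0.0
    return score, score > threshold
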