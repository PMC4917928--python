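"""Noise-resilience (degeneration) assays for coherence metrics.

A family is progressively degenerated by replacing a fraction of its
members with proteins drawn at random from a disjoint pool (in practice,
the union of all other loaded families).  Each configured metric is scored
on every degenerate set, and per-level means and standard deviations over
iterations form the family's degeneration profile — the similarity-vs-noise
curve from which a metric's noise resilience and resolution (max-min of the
reported means) are read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations import AnnotationCorpus, ICTable
from .enrichment import DEFAULT_ALPHA
from .hybrid import build_shadow, m_gic, m_ui
from .metrics import ProteinSet, agreement, make_pairwise, set_similarity
from .ontology import Ontology

logger = logging.getLogger("funcoh")

DEFAULT_LEVELS = tuple(np.round(np.arange(0.0, 1.01, 0.1), 10))
DEFAULT_ITERATIONS = 100
DEFAULT_MIN_FAMILY_SIZE = 20

BUILTIN_METRICS = ("agreement", "ui", "gic", "mui", "mgic")

# Plug-in hook for external set metrics (e.g. a GS2 implementation):
# name -> callable(protein_set, corpus, context_dict) -> float in [0, 1].
EXTRA_METRICS: dict[str, Callable[[ProteinSet, AnnotationCorpus, dict], float]] = {}


def register_metric(
    name: str, fn: Callable[[ProteinSet, AnnotationCorpus, dict], float]
) -> None:
    """Register an external set-level metric under ``name`` for assays."""
    if name in BUILTIN_METRICS:
        raise ValueError(f"{name!r} is a built-in metric name")
    EXTRA_METRICS[name] = fn


class AssayError(Exception):
    pass


class PoolError(AssayError):
    """Replacement pool too small or not disjoint from the family."""


@dataclass(frozen=True)
class AssayConfig:
    """Degeneration assay settings.

    levels: replacement fractions in [0, 1], ascending (default 0 to 1 in
    steps of 0.1); iterations: degenerate sets scored per level (default
    100); seed: master seed for the single documented random stream;
    min_family_size: families below this are skipped; metrics: metric
    names to score; alpha: enrichment significance for the hybrid metrics.
    """

    levels: tuple[float, ...] = DEFAULT_LEVELS
    iterations: int = DEFAULT_ITERATIONS
    seed: int = 0
    min_family_size: int = DEFAULT_MIN_FAMILY_SIZE
    metrics: tuple[str, ...] = BUILTIN_METRICS
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        if any(not 0.0 <= lv <= 1.0 for lv in self.levels):
            raise ValueError("levels must lie in [0, 1]")
        if list(self.levels) != sorted(self.levels):
            raise ValueError("levels must be sorted ascending")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class DegenerationProfile:
    """Per (level, metric) mean and dispersion for one family."""

    family: str
    table: pd.DataFrame  # columns: metric, level, mean, sd, n

    def mean_by_level(self, metric: str) -> dict[float, float]:
        sub = self.table[self.table["metric"] == metric]
        return dict(zip(sub["level"], sub["mean"]))

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out.insert(0, "family", self.family)
        return out


def replacement_count(fraction: float, n: int) -> int:
    """Number of members to replace: round half up of fraction*n."""
    return int(np.floor(fraction * n + 0.5))


def degenerate(
    family: ProteinSet,
    pool: ProteinSet,
    fraction: float,
    rng: np.random.Generator,
) -> ProteinSet:
    """Replace a fraction of the family with random pool proteins.

    Keeps N−k members sampled without replacement from the family and adds
    k sampled without replacement from the pool, k = round(fraction·N)
    half-up.  Fraction 0 returns the family unchanged; fraction 1 yields a
    set disjoint from the family.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    overlap = set(family.members) & set(pool.members)
    if overlap:
        raise PoolError(f"pool overlaps family: {sorted(overlap)[:5]}")
    n = len(family)
    k = replacement_count(fraction, n)
    if k > len(pool):
        raise PoolError(f"pool of {len(pool)} cannot supply {k} replacements")
    if k == 0:
        return family
    if k < n:
        keep_idx = rng.choice(n, size=n - k, replace=False)
        kept = [family.members[i] for i in sorted(keep_idx)]
    else:
        kept = []
    draw_idx = rng.choice(len(pool), size=k, replace=False)
    drawn = [pool.members[i] for i in sorted(draw_idx)]
    return ProteinSet.from_ids(kept + drawn, label=family.label)


def make_pool(
    families: Mapping[str, ProteinSet], target: str
) -> ProteinSet:
    """Union of all loaded families except the target, as the noise source."""
    members: list[str] = []
    seen: set[str] = set(families[target].members)
    for label in sorted(families):
        if label == target:
            continue
        for p in families[label].members:
            if p not in seen:
                seen.add(p)
                members.append(p)
    if not members:
        raise PoolError(f"no pool proteins outside family {target!r}")
    return ProteinSet.from_ids(members, label=f"pool-minus-{target}")


def score_set(
    protein_set: ProteinSet,
    corpus: AnnotationCorpus,
    ontology: Ontology,
    ic: ICTable,
    metric_names: Sequence[str],
    alpha: float = DEFAULT_ALPHA,
) -> dict[str, float]:
    """Score one protein set under every requested metric.

    The enrichment step is shared between mUI and mGIC when both are
    requested, since they filter through the same shadow graph.
    """
    scores: dict[str, float] = {}
    shadow = None
    for name in metric_names:
        if name == "agreement":
            scores[name] = agreement(protein_set, corpus)
        elif name in ("ui", "gic"):
            pairwise = make_pairwise(name, ic=ic)
            scores[name] = set_similarity(protein_set, corpus, pairwise).value
        elif name in ("mui", "mgic"):
            if shadow is None:
                shadow = build_shadow(protein_set, corpus, ontology, alpha=alpha)
            if name == "mui":
                scores[name] = m_ui(
                    protein_set, corpus, ontology, alpha=alpha, shadow=shadow
                ).value
            else:
                scores[name] = m_gic(
                    protein_set, corpus, ontology, ic, alpha=alpha, shadow=shadow
                ).value
        elif name in EXTRA_METRICS:
            ctx = {"ontology": ontology, "ic": ic, "alpha": alpha}
            scores[name] = EXTRA_METRICS[name](protein_set, corpus, ctx)
        else:
            raise ValueError(f"unknown metric {name!r}")
    return scores


def run_assay(
    family: ProteinSet,
    pool: ProteinSet,
    corpus: AnnotationCorpus,
    ontology: Ontology,
    ic: ICTable,
    config: AssayConfig,
) -> DegenerationProfile | None:
    """Run the degeneration assay for one family.

    For each level x iteration the family is degenerated and every
    configured metric scored; the profile holds per-level means and
    standard deviations (ddof=0).  Reproducible from ``config.seed``: each
    (level, iteration) cell draws from its own substream spawned from the
    master seed, so results are independent of execution order.  Families
    below ``config.min_family_size`` are skipped with a logged reason.
    """
    if len(family) < config.min_family_size:
        logger.warning(
            "skipping family %r: size %d below minimum %d",
            family.label, len(family), config.min_family_size,
        )
        return None
    rows = []
    for li, level in enumerate(config.levels):
        per_metric: dict[str, list[float]] = {m: [] for m in config.metrics}
        for it in range(config.iterations):
            ss = np.random.SeedSequence([config.seed, li, it])
            rng = np.random.Generator(np.random.PCG64(ss))
            degraded = degenerate(family, pool, level, rng)
            scores = score_set(
                degraded, corpus, ontology, ic, config.metrics, alpha=config.alpha
            )
            for m, v in scores.items():
                per_metric[m].append(v)
        for m in config.metrics:
            vals = np.asarray(per_metric[m], dtype=float)
            rows.append(
                {
                    "metric": m,
                    "level": level,
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=0)),
                    "n": len(vals),
                }
            )
    return DegenerationProfile(family=family.label, table=pd.DataFrame(rows))


def resolution(
    profile_rows: Iterable[Mapping[float, float]] | Iterable[DegenerationProfile],
    metric: str | None = None,
) -> float:
    """Average per-family range (max−min) of mean similarity across levels.

    Accepts either plain per-family ``{level: mean}`` maps, or
    :class:`DegenerationProfile` objects together with a metric name.
    """
    ranges: list[float] = []
    for entry in profile_rows:
        if isinstance(entry, DegenerationProfile):
            if metric is None:
                raise ValueError("metric name required with DegenerationProfile input")
            by_level = entry.mean_by_level(metric)
        else:
            by_level = dict(entry)
        if len(by_level) < 2:
            raise ValueError("each family profile needs at least 2 levels")
        means = list(by_level.values())
        ranges.append(max(means) - min(means))
    if not ranges:
        raise ValueError("no family profiles given")
    return float(np.mean(ranges))


def profiles_to_frame(profiles: Iterable[DegenerationProfile]) -> pd.DataFrame:
    """Concatenate family profiles into one tidy table."""
    frames = [p.to_frame() for p in profiles if p is not None]
    if not frames:
        return pd.DataFrame(columns=["family", "metric", "level", "mean", "sd", "n"])
    return pd.concat(frames, ignore_index=True)


def plot_profile(profile: DegenerationProfile, path: str) -> None:
    """Write a similarity-vs-noise line plot (one line per metric) as PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for metric, sub in profile.table.groupby("metric"):
        sub = sub.sort_values("level")
        ax.errorbar(
            sub["level"] * 100, sub["mean"], yerr=sub["sd"], label=metric,
            marker="o", markersize=3, capsize=2,
        )
    ax.set_xlabel("random replacement (%)")
    ax.set_ylabel("mean similarity")
    ax.set_ylim(-0.02, 1.02)
    ax.set_title(profile.family)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
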