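"""Equally-weighted multi-study prevalence statistics.

Amplicon surveys differ wildly in sample count, so pooling samples lets
large studies dominate. The statistics here instead weight every study
equally: per-study mean relative abundance (RA) and frequency of
occurrence (FO) are computed first, then averaged across studies without
regard to sample counts. A taxon is "dominant" when its equally-weighted
RA exceeds 0.1% and "common" when its equally-weighted FO exceeds 30%;
the "core" is their intersection.

Study saturation is assessed with permutation-based accumulation curves:
the expected number of distinct taxa seen after sampling k studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class StudyTable:
    """One study's samples x taxa relative-abundance matrix.

    ``abundances`` holds fractions (not percents); rows may sum to less
    than 1 when part of a sample is unclassified. ``read_counts`` is an
    optional per-sample total used only for QC filtering.
    """

    study_id: str
    abundances: pd.DataFrame
    read_counts: pd.Series | None = None

    def __post_init__(self):
        if (self.abundances.values < 0).any():
            raise ValueError(f"{self.study_id}: negative abundances")
        sums = self.abundances.sum(axis=1)
        if (sums > 1 + 1e-9).any():
            raise ValueError(f"{self.study_id}: sample abundances sum to > 1")
        if self.read_counts is not None and not self.read_counts.index.equals(
            self.abundances.index
        ):
            raise ValueError(f"{self.study_id}: read_counts index mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.abundances)

    @property
    def taxa(self) -> list[str]:
        return list(self.abundances.columns)


@dataclass(frozen=True)
class TaxonPrevalence:
    taxon: str
    per_study_mean_ra: tuple[float, ...]
    per_study_fo: tuple[float, ...]     # percents
    ew_ra: float                        # fraction
    ew_fo: float                        # percent


def qc_filter(table: StudyTable, min_reads: int = 10_000) -> StudyTable:
    """Drop samples with fewer than ``min_reads`` reads (strict <); a sample
    with exactly min_reads is retained."""
    if table.read_counts is None:
        raise ValueError(
            f"{table.study_id}: read counts are required for QC filtering"
        )
    keep = table.read_counts >= min_reads
    return StudyTable(
        study_id=table.study_id,
        abundances=table.abundances.loc[keep],
        read_counts=table.read_counts.loc[keep],
    )


def study_summary(table: StudyTable, min_ra: float = 0.0) -> pd.DataFrame:
    """Per-taxon mean RA and FO for one study.

    FO = 100 x (samples with RA > min_ra) / n_samples; the default
    presence floor is 0, i.e. any nonzero abundance counts as detection.
    The mean RA includes samples where the taxon is absent.
    """
    if table.n_samples == 0:
        raise ValueError(f"{table.study_id}: no samples")
    ab = table.abundances
    return pd.DataFrame(
        {
            "mean_ra": ab.mean(axis=0),
            "fo": 100.0 * (ab > min_ra).mean(axis=0),
        }
    ).rename_axis("taxon")


def equally_weighted(summaries: list[pd.DataFrame]) -> list[TaxonPrevalence]:
    """Equally-weighted average RA and FO across per-study summaries.

    Each study contributes with weight 1/n_studies regardless of its
    sample count; a taxon absent from a study's table contributes
    mean_ra = 0 and fo = 0 for that study.
    """
    if not summaries:
        raise ValueError("at least one study summary is required")
    taxa: list[str] = []
    for s in summaries:
        for t in s.index:
            if t not in taxa:
                taxa.append(t)
    result = []
    for taxon in taxa:
        ras = tuple(
            float(s.loc[taxon, "mean_ra"]) if taxon in s.index else 0.0
            for s in summaries
        )
        fos = tuple(
            float(s.loc[taxon, "fo"]) if taxon in s.index else 0.0
            for s in summaries
        )
        result.append(
            TaxonPrevalence(
                taxon=taxon,
                per_study_mean_ra=ras,
                per_study_fo=fos,
                ew_ra=float(np.mean(ras)),
                ew_fo=float(np.mean(fos)),
            )
        )
    return result


def classify_taxa(
    prevalences: list[TaxonPrevalence],
    ra_thresh: float = 0.001,
    fo_thresh: float = 30.0,
) -> dict[str, set[str]]:
    """Dominant (ew RA > 0.1%), common (ew FO > 30%), and core
    (dominant AND common) taxa. Both boundaries are strict."""
    dominant = {p.taxon for p in prevalences if p.ew_ra > ra_thresh}
    common = {p.taxon for p in prevalences if p.ew_fo > fo_thresh}
    return {
        "dominant": dominant,
        "common": common,
        "core": dominant & common,
    }


def accumulation_curve(
    summaries: list[pd.DataFrame],
    n_perm: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation accumulation curve of taxon richness over studies.

    The value at k is the mean, over ``n_perm`` random study orderings, of
    the number of distinct taxa detected (fo > 0) in the first k studies.
    The endpoint at k = n_studies equals the union richness exactly for
    every permutation. Returns a DataFrame with columns k, mean, sd.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    detected = [frozenset(s.index[s["fo"] > 0]) for s in summaries]
    n = len(detected)
    rng = np.random.default_rng(seed)
    richness = np.empty((n_perm, n), dtype=float)
    for p in range(n_perm):
        order = rng.permutation(n)
        seen: set = set()
        for k, idx in enumerate(order):
            seen |= detected[idx]
            richness[p, k] = len(seen)
    return pd.DataFrame(
        {
            "k": np.arange(1, n + 1),
            "mean": richness.mean(axis=0),
            "sd": richness.std(axis=0, ddof=0),
        }
    )
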