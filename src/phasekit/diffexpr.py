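"""Two-library differential analysis by g-test.

The g-test (likelihood-ratio goodness of fit, ``G = 2 * sum O * ln(O/E)``,
chi-square distributed under the null) is applied at several levels: distinct
sequence, phased locus, annotation class, and miRNA family.  The design is
two bulked libraries with no replicates, as in single-pool comparative small
RNA-seq experiments: expected counts are proportional to library totals, a
fixed p-value threshold (default 1e-3) is used without multiple-testing
correction, and RPM values are used only for fold-ratio reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from phasekit.phasing import PhasedLocus
from phasekit.synthgen import ReferenceBundle


@dataclass
class GTestResult:
    G: float
    df: int
    p_value: float


def gtest(
    observed: Sequence[float],
    expected: Sequence[float],
    df: int = 1,
) -> GTestResult:
    """Likelihood-ratio goodness-of-fit test of observed against expected.

    Expected counts are rescaled internally to the observed total, so only
    their proportions matter.  ``0 * ln(0)`` is taken as 0; any zero expected
    cell with a nonzero observation is an input error.
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape:
        raise ValueError("observed and expected must have the same length")
    if np.any(obs < 0):
        raise ValueError("observed counts must be non-negative")
    if np.any((exp <= 0) & (obs > 0)):
        raise ValueError("zero/negative expected count with nonzero observation")
    total = obs.sum()
    if total == 0:
        return GTestResult(0.0, df, 1.0)
    exp = exp * (total / exp.sum())
    nz = obs > 0
    G = 2.0 * float(np.sum(obs[nz] * np.log(obs[nz] / exp[nz])))
    G = max(G, 0.0)
    return GTestResult(G, df, float(chi2.sf(G, df)))


def _fold_ratio(rpm_a: float, rpm_b: float, count_a: int, count_b: int,
                pseudocount: float) -> float:
    """RPM fold ratio A/B; a pseudocount keeps it defined when a count is 0."""
    if count_a == 0 or count_b == 0:
        rpm_a, rpm_b = rpm_a + pseudocount, rpm_b + pseudocount
    return rpm_a / rpm_b


def unit_differential(
    units: pd.DataFrame,
    totals: Mapping[str, int],
    alpha: float = 1e-3,
    fold: float = 5.0,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-unit two-library g-test with fold categorisation.

    ``units`` needs columns ``unit_id, count_A, count_B, rpm_A, rpm_B``.  For
    each unit the observed (count_A, count_B) pair is tested (df=1) against
    expectations proportional to the library totals; ``category`` is ``ns``
    when p > alpha, otherwise ``over_A`` / ``over_B`` by the direction of the
    RPM ratio, and ``fold5_flag`` marks an RPM ratio of at least ``fold`` in
    either direction.
    """
    ta, tb = float(totals["A"]), float(totals["B"])
    if ta <= 0 or tb <= 0:
        raise ValueError("library totals must be positive")
    rows = []
    for rec in units.itertuples(index=False):
        res = gtest([rec.count_A, rec.count_B], [ta, tb], df=1)
        ratio = _fold_ratio(rec.rpm_A, rec.rpm_B, rec.count_A, rec.count_B, pseudocount)
        if res.p_value > alpha:
            category = "ns"
        else:
            category = "over_A" if rec.rpm_A > rec.rpm_B else "over_B"
        rows.append(
            dict(unit_id=rec.unit_id, count_A=rec.count_A, count_B=rec.count_B,
                 rpm_A=rec.rpm_A, rpm_B=rec.rpm_B, ratio=ratio, G=res.G,
                 p_value=res.p_value, category=category,
                 fold5_flag=bool(ratio >= fold or ratio <= 1.0 / fold))
        )
    return pd.DataFrame(
        rows, columns=["unit_id", "count_A", "count_B", "rpm_A", "rpm_B", "ratio",
                       "G", "p_value", "category", "fold5_flag"]
    )


def class_enrichment(
    subset_counts: Mapping[str, int],
    background_counts: Mapping[str, int],
    alpha: float = 1e-3,
) -> pd.DataFrame:
    """Per-class 2x2 g-test of a subset against the rest of the background.

    For every class the table (class / other) x (subset / rest) is tested
    with df=1; the direction column says whether the class is over- or
    under-represented in the subset.  The subset must be contained in the
    background.
    """
    classes = sorted(background_counts)
    n_sub = sum(subset_counts.values())
    n_bg = sum(background_counts.values())
    if n_sub > n_bg:
        raise ValueError("subset larger than background")
    rows = []
    for cls in classes:
        a = subset_counts.get(cls, 0)
        b = n_sub - a
        c = background_counts[cls] - a
        d = (n_bg - n_sub) - c
        if min(a, b, c, d) < 0:
            raise ValueError(f"subset not contained in background for class {cls!r}")
        obs = np.array([a, b, c, d], dtype=float)
        row = obs[:2].sum(), obs[2:].sum()
        col = a + c, b + d
        total = obs.sum()
        if total == 0 or 0 in row or 0 in col:
            res = GTestResult(0.0, 1, 1.0)  # degenerate margin: no information
        else:
            exp = np.array([row[0] * col[0], row[0] * col[1],
                            row[1] * col[0], row[1] * col[1]]) / total
            res = gtest(obs, exp, df=1)
        sub_frac = a / n_sub if n_sub else 0.0
        bg_frac = (a + c) / n_bg if n_bg else 0.0
        direction = "over" if sub_frac > bg_frac else (
            "under" if sub_frac < bg_frac else "none")
        rows.append(
            dict(annotation_class=cls, subset_n=a, subset_frac=sub_frac,
                 background_n=a + c, background_frac=bg_frac, G=res.G,
                 p_value=res.p_value,
                 direction=direction if res.p_value <= alpha else "ns")
        )
    return pd.DataFrame(rows)


def mirna_family_profile(
    distincts: pd.DataFrame,
    bundle: ReferenceBundle,
    loci: Sequence[PhasedLocus],
    length_range: tuple[int, int] = (19, 25),
) -> pd.DataFrame:
    """Per-family abundance profile of miRNA-class sequences.

    Families are taken from the database record each sequence matched during
    annotation (``annotation_subject``); sequences without a family land in
    an ``unassigned`` bucket.  Each family is typed from database metadata
    (canonical / variant / siRNA-like), its modal length is the read length
    with the highest summed abundance (RPM), and ``phased_overlap_flag``
    marks families whose database locus coordinates overlap a detected
    phased locus.
    """
    mir = distincts[distincts["annotation_class"] == "miRNA"]
    lo, hi = length_range
    locus_spans = [(lc.chrom, lc.start, lc.end) for lc in loci]
    fam_feats: dict[str, list] = {}
    for f in bundle.feature_intervals.get("miRNA", []):
        fam = bundle.mirna_families.get(f.name)
        if fam:
            fam_feats.setdefault(fam, []).append(f)

    rows = []
    if len(mir):
        fam_col = mir["annotation_subject"].map(bundle.mirna_families).fillna("unassigned")
    else:
        fam_col = pd.Series(dtype=object)
    for fam, grp in mir.groupby(fam_col):
        hist = {
            length: float(sub["rpm_A"].sum() + sub["rpm_B"].sum())
            for length, sub in grp.groupby("length")
            if lo <= length <= hi
        }
        modal = max(sorted(hist), key=lambda length: hist[length]) if hist else 0
        overlap = any(
            f.chrom == chrom and f.start < e and s < f.end
            for f in fam_feats.get(fam, [])
            for chrom, s, e in locus_spans
        )
        rows.append(
            dict(family=fam, n_sequences=len(grp),
                 family_type=bundle.family_types.get(fam, "canonical"),
                 count_A=int(grp["count_A"].sum()), count_B=int(grp["count_B"].sum()),
                 modal_length=modal,
                 length_histogram=";".join(f"{k}:{hist[k]:.3f}" for k in sorted(hist)),
                 phased_overlap_flag=overlap)
        )
    return pd.DataFrame(
        rows, columns=["family", "n_sequences", "family_type", "count_A", "count_B",
                       "modal_length", "length_histogram", "phased_overlap_flag"]
    )
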