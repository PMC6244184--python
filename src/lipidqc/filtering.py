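"""Collapse adduct/mode redundancy and filter by QC reproducibility.

One lipid can be detected as several adducts in both electrospray
polarities.  For statistical analysis each lipid must appear exactly once,
so: (1) within each mode the adduct with the lowest QC RSD wins; (2) for
lipids detected in both modes, the lower-RSD mode wins, and the Spearman
correlation between the two candidates across non-blank samples is reported
(a rho >= 0.80 flag is descriptive only, never a removal criterion);
(3) ions with QC RSD above 25% ("more than", strict) are removed, as are
internal standards, which are calibration devices rather than analytes.
The final matrix is keyed by lipid id and shipped with a data dictionary.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import stats

from .library import IonDatabase
from .matrix import FeatureMatrix

__all__ = [
    "rsd",
    "qc_rsd_per_ion",
    "AdductGroup",
    "select_adduct_within_mode",
    "dedup_across_modes",
    "collapse_lipids",
    "apply_rsd_filter",
    "build_data_dictionary",
    "filter_features",
    "FilterResult",
    "SPEARMAN_CONCORDANCE_THRESHOLD",
    "DEFAULT_RSD_THRESHOLD",
]

SPEARMAN_CONCORDANCE_THRESHOLD = 0.80
DEFAULT_RSD_THRESHOLD = 25.0  # percent
_MODE_RANK = {"positive": 0, "negative": 1}


def rsd(values) -> float:
    """Relative standard deviation in percent: 100 * sd(n-1) / mean."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 2:
        raise ValueError(f"RSD needs at least 2 finite values, got {len(v)}")
    mean = v.mean()
    if mean == 0:
        return math.nan  # undefined; callers treat NaN as flagged
    return 100.0 * v.std(ddof=1) / mean


def qc_rsd_per_ion(fm: FeatureMatrix) -> pd.Series:
    """QC RSD per ion; NaN where undefined (zero mean or < 2 QC values)."""
    qc = fm.qc_values()
    out = {}
    for ion_id in fm.ion_ids:
        v = qc[ion_id].to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        try:
            out[ion_id] = rsd(v)
        except ValueError:
            out[ion_id] = math.nan
    return pd.Series(out, name="qc_rsd")


def _tie_key(ion_row: pd.Series, ion_id: str, value: float) -> tuple:
    # NaN RSD loses to any defined RSD; ties break deterministically by
    # mode (positive first), adduct label, then ion_id.
    return (
        math.isnan(value),
        value if not math.isnan(value) else math.inf,
        _MODE_RANK.get(ion_row["mode"], 2),
        str(ion_row["adduct"]),
        str(ion_id),
    )


@dataclasses.dataclass
class AdductGroup:
    """Selection record for one lipid."""

    lipid_id: str
    members: dict[str, list[str]]  # mode -> ion_ids
    member_rsd: dict[str, float]
    selected_per_mode: dict[str, str | None]
    final_ion: str | None
    spearman_rho: float | None = None
    concordant: bool | None = None


def select_adduct_within_mode(
    member_ions: list[str],
    qc_rsd: pd.Series,
    ions: pd.DataFrame,
) -> str | None:
    """The member with minimal QC RSD; None when every member is undefined."""
    defined = [m for m in member_ions if not math.isnan(qc_rsd.get(m, math.nan))]
    if not defined:
        return None
    return min(
        member_ions,
        key=lambda m: _tie_key(ions.loc[m], m, float(qc_rsd.get(m, math.nan))),
    )


def dedup_across_modes(
    selected_per_mode: dict[str, str | None],
    qc_rsd: pd.Series,
    nonblank_values: pd.DataFrame,
    ions: pd.DataFrame,
) -> tuple[str | None, float | None]:
    """Lower-RSD winner of the per-mode candidates + cross-mode Spearman rho.

    rho is computed between the two candidates' peak heights across all
    non-blank samples and is None for single-mode lipids.
    """
    candidates = [i for i in selected_per_mode.values() if i is not None]
    if not candidates:
        return None, None
    rho = None
    if len(candidates) == 2:
        a, b = candidates
        res = stats.spearmanr(
            nonblank_values[a], nonblank_values[b], nan_policy="omit"
        )
        rho = float(res.statistic)
    winner = min(
        candidates,
        key=lambda m: _tie_key(ions.loc[m], m, float(qc_rsd.get(m, math.nan))),
    )
    return winner, rho


def collapse_lipids(
    fm: FeatureMatrix, qc_rsd: pd.Series | None = None
) -> tuple[pd.DataFrame, list[AdductGroup]]:
    """One ion per lipid by lowest QC RSD; returns (selection table, groups)."""
    if qc_rsd is None:
        qc_rsd = qc_rsd_per_ion(fm)
    nonblank = fm.nonblank_values()
    groups: list[AdductGroup] = []
    rows = []
    lipid_order = list(dict.fromkeys(fm.ions["lipid_id"]))
    for lipid_id in lipid_order:
        member_ids = [
            i for i in fm.ion_ids if fm.ions.loc[i, "lipid_id"] == lipid_id
        ]
        by_mode: dict[str, list[str]] = {}
        for i in member_ids:
            by_mode.setdefault(fm.ions.loc[i, "mode"], []).append(i)
        selected = {
            mode: select_adduct_within_mode(members, qc_rsd, fm.ions)
            for mode, members in by_mode.items()
        }
        final, rho = dedup_across_modes(selected, qc_rsd, nonblank, fm.ions)
        group = AdductGroup(
            lipid_id=lipid_id,
            members=by_mode,
            member_rsd={i: float(qc_rsd.get(i, math.nan)) for i in member_ids},
            selected_per_mode=selected,
            final_ion=final,
            spearman_rho=rho,
            concordant=(
                None if rho is None else bool(rho >= SPEARMAN_CONCORDANCE_THRESHOLD)
            ),
        )
        groups.append(group)
        rows.append(
            dict(
                lipid_id=lipid_id,
                n_members=len(member_ids),
                selected_positive=selected.get("positive"),
                selected_negative=selected.get("negative"),
                final_ion=final,
                final_qc_rsd=(
                    float(qc_rsd.get(final, math.nan)) if final else math.nan
                ),
                spearman_rho=rho,
                concordant=group.concordant,
            )
        )
    return pd.DataFrame(rows), groups


def apply_rsd_filter(
    fm: FeatureMatrix,
    qc_rsd: pd.Series | None = None,
    threshold: float = DEFAULT_RSD_THRESHOLD,
) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Drop ions whose QC RSD exceeds the threshold (strict ">"), and all
    internal standards regardless of RSD.  Boundary values are retained.
    Returns the filtered matrix and a removal log (ion, RSD, reason)."""
    if qc_rsd is None:
        qc_rsd = qc_rsd_per_ion(fm)
    removed = []
    keep = []
    for ion_id in fm.ion_ids:
        value = float(qc_rsd.get(ion_id, math.nan))
        if bool(fm.ions.loc[ion_id, "is_internal_standard"]):
            removed.append(dict(ion_id=ion_id, qc_rsd=value, reason="internal_standard"))
        elif not math.isnan(value) and value > threshold:
            removed.append(dict(ion_id=ion_id, qc_rsd=value, reason="qc_rsd_above_threshold"))
        else:
            keep.append(ion_id)
    filtered = FeatureMatrix(
        values=fm.values[keep].copy(),
        samples=fm.samples.copy(),
        ions=fm.ions.loc[keep].copy(),
        provenance=fm.provenance + f"+rsd_filtered({threshold:g}%)",
        snr=None if fm.snr is None else fm.snr[keep].copy(),
        apex_rt=None if fm.apex_rt is None else fm.apex_rt[keep].copy(),
    )
    log = pd.DataFrame(removed, columns=["ion_id", "qc_rsd", "reason"])
    return filtered, log


def build_data_dictionary(fm: FeatureMatrix, db: IonDatabase) -> pd.DataFrame:
    """One dictionary row per final-matrix ion, joined from the database."""
    rows = []
    for ion_id in fm.ion_ids:
        if ion_id not in db:
            raise ValueError(f"ion {ion_id!r} missing from the target database")
        ion = db.get(ion_id)
        rows.append(
            dict(
                lipid_id=ion.lipid_id,
                ion_id=ion.ion_id,
                name=ion.name,
                mode=ion.mode,
                adduct=ion.adduct,
                mz=ion.mz,
                expected_rt=ion.expected_rt,
                inchikey=ion.inchikey,
                is_known=ion.is_known,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "lipid_id", "ion_id", "name", "mode", "adduct", "mz",
            "expected_rt", "inchikey", "is_known",
        ],
    )


@dataclasses.dataclass
class FilterResult:
    matrix: FeatureMatrix  # final matrix, columns keyed by lipid_id
    dictionary: pd.DataFrame
    selection: pd.DataFrame
    removal_log: pd.DataFrame
    qc_rsd: pd.Series
    groups: list[AdductGroup]


def filter_features(
    fm: FeatureMatrix,
    db: IonDatabase,
    threshold: float = DEFAULT_RSD_THRESHOLD,
) -> FilterResult:
    """Full filtering stage on a normalized matrix.

    Adduct/mode collapse first, then the RSD filter (which also removes
    internal standards); the surviving columns are relabeled by lipid id in
    the final matrix, matching the shape of a subject x lipid data product.
    """
    qc_rsd = qc_rsd_per_ion(fm)
    selection, groups = collapse_lipids(fm, qc_rsd)
    final_ions = [g.final_ion for g in groups if g.final_ion is not None]
    dropped_lipids = [g.lipid_id for g in groups if g.final_ion is None]
    collapsed = FeatureMatrix(
        values=fm.values[final_ions].copy(),
        samples=fm.samples.copy(),
        ions=fm.ions.loc[final_ions].copy(),
        provenance=fm.provenance + "+adduct_collapsed",
        snr=None if fm.snr is None else fm.snr[final_ions].copy(),
        apex_rt=None if fm.apex_rt is None else fm.apex_rt[final_ions].copy(),
    )
    filtered, removal_log = apply_rsd_filter(collapsed, qc_rsd, threshold)
    if dropped_lipids:
        removal_log = pd.concat(
            [
                removal_log,
                pd.DataFrame(
                    [
                        dict(ion_id=lid, qc_rsd=math.nan, reason="all_members_undefined_rsd")
                        for lid in dropped_lipids
                    ]
                ),
            ],
            ignore_index=True,
        )
    # relabel by lipid id (one ion per lipid after collapse, so bijective)
    ion_to_lipid = {i: filtered.ions.loc[i, "lipid_id"] for i in filtered.ion_ids}
    final = FeatureMatrix(
        values=filtered.values.rename(columns=ion_to_lipid),
        samples=filtered.samples.copy(),
        ions=filtered.ions.set_index(
            filtered.ions["lipid_id"].rename("ion_id"), drop=False
        ),
        provenance=filtered.provenance + "+lipid_keyed",
    )
    dictionary = build_data_dictionary(filtered, db)
    return FilterResult(
        matrix=final,
        dictionary=dictionary,
        selection=selection,
        removal_log=removal_log,
        qc_rsd=qc_rsd,
        groups=groups,
    )
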