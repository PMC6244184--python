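"""Synthetic LC-MS run generator with known ground truth.

Emulates the acquisition design of a multi-batch serum lipidomics study so the
whole post-processing chain can be exercised and verified without restricted
cohort data: study samples randomized across four batches, one pooled-plasma
QC injection closing every block of ten study samples, one extraction blank
per ten study samples, randomly inserted replicate pairs, smooth per-batch
multiplicative intensity drift, per-sample quadratic retention-time
distortion, lognormal measurement noise, Gaussian chromatographic peaks on a
noisy baseline, and lipids detectable as several adducts in both polarities
with correlated signals (they share the lipid's true concentration).

All randomness flows from one master seed through named substreams (plan,
database, concentrations, responses, drift, retention times, noise,
baseline), so each stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .library import (
    IonDatabase,
    TargetIon,
    adduct_mz,
    display_mz,
    load_ion_database,
    tg_formula,
)

__all__ = [
    "RunParameters",
    "InjectionPlan",
    "GroundTruth",
    "EICSet",
    "SimulationError",
    "build_injection_sequence",
    "make_synthetic_database",
    "simulate_true_concentrations",
    "simulate_eics",
    "simulate_run",
    "write_run",
    "read_run",
]


class SimulationError(RuntimeError):
    pass


# named substreams off the master seed
_STREAM_PLAN = 11
_STREAM_DB = 12
_STREAM_CONC = 13
_STREAM_RESP = 14
_STREAM_DRIFT = 15
_STREAM_RT = 16
_STREAM_NOISE = 17
_STREAM_BASELINE = 18


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


@dataclasses.dataclass
class RunParameters:
    """Tunable statistical structure of a simulated acquisition.

    Intensity drift is multiplicative (instrument response scaling) and, by
    default, linear in injection order within each batch with a random slope
    per (ion, batch); ``drift_amplitude`` is the peak fractional excursion.
    ``batch_scale_sigma`` is the lognormal sigma of an additional constant
    response factor per (ion, batch), the between-batch effect that median
    normalization removes.  Measurement noise is lognormal with coefficient
    of variation ``noise_cv``.  Retention-time distortion is a per-sample
    quadratic observed = a*rt**2 + b*rt + c with b near 1.
    """

    drift_amplitude: float = 0.20
    drift_shape: str = "linear"  # "linear" | "quadratic"
    batch_scale_sigma: float = 0.15
    noise_cv: float = 0.08
    biological_cv: float = 0.35
    rt_quad_sd: float = 3e-5  # sd of a (min^-1)
    rt_slope_sd: float = 1e-3  # sd of b - 1
    rt_shift_sd: float = 0.008  # sd of c (min)
    peak_width_sd: float = 0.02  # chromatographic Gaussian sd (min)
    baseline_level: float = 50.0  # counts
    baseline_noise: float = 5.0  # counts (sd)
    carryover_fraction: float = 0.02  # blank peak as fraction of preceding QC
    rt_grid_step: float = 0.005  # min (~2 spectra/s)
    mean_log10_height: tuple[float, float] = (4.0, 5.5)
    response_low: float = 0.3  # lower bound of adduct response factors
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "drift_amplitude",
            "batch_scale_sigma",
            "noise_cv",
            "biological_cv",
            "baseline_level",
            "baseline_noise",
            "carryover_fraction",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.rt_grid_step <= 0:
            raise ValueError("rt_grid_step must be positive")
        if self.peak_width_sd <= 0:
            raise ValueError("peak_width_sd must be positive")
        if self.drift_shape not in ("linear", "quadratic"):
            raise ValueError("drift_shape must be 'linear' or 'quadratic'")


# ---------------------------------------------------------------------------
# Injection plan
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class InjectionPlan:
    """Ordered injection sequence with batch, type and duplicate links.

    Batches are built from contiguous QC-bracketed blocks: every block of
    ``qc_interval`` study samples is closed by one pooled-QC injection (a
    partial final block still gets its closing QC), and one blank follows
    per ``blank_interval`` study samples.
    """

    records: pd.DataFrame  # sample_id, sample_type, batch, injection_order, duplicate_of
    n_batches: int
    qc_interval: int
    blank_interval: int

    def __post_init__(self) -> None:
        rec = self.records
        orders = rec["injection_order"].to_numpy()
        if len(orders) and (
            len(np.unique(orders)) != len(orders) or np.any(np.diff(orders) <= 0)
        ):
            raise ValueError("injection_order must be strictly increasing and unique")
        batches = rec["batch"].to_numpy()
        if len(batches) and np.any(np.diff(batches) < 0):
            raise ValueError("batches must be contiguous in injection order")
        study_ids = set(rec.loc[rec["sample_type"] == "study", "sample_id"])
        refs = [d for d in rec["duplicate_of"] if isinstance(d, str) and d]
        if len(refs) != len(set(refs)):
            raise ValueError("a study sample may be duplicated at most once")
        for ref in refs:
            if ref not in study_ids:
                raise ValueError(f"duplicate_of references unknown study sample {ref!r}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.records["sample_id"])

    def of_type(self, sample_type: str) -> pd.DataFrame:
        return self.records[self.records["sample_type"] == sample_type]

    @property
    def duplicate_pairs(self) -> list[tuple[str, str]]:
        pairs = []
        for _, row in self.records.iterrows():
            if isinstance(row["duplicate_of"], str) and row["duplicate_of"]:
                pairs.append((row["duplicate_of"], row["sample_id"]))
        return pairs

    def annotations(self) -> pd.DataFrame:
        """Sample annotation table indexed by sample_id."""
        return self.records.set_index("sample_id", drop=False)[
            ["sample_type", "batch", "injection_order", "duplicate_of"]
        ]

    def batch_position(self) -> pd.Series:
        """Normalized position t in [0, 1] of each injection within its batch."""
        rec = self.records
        t = pd.Series(0.5, index=rec["sample_id"], dtype=float)
        for _, grp in rec.groupby("batch"):
            lo, hi = grp["injection_order"].min(), grp["injection_order"].max()
            span = max(hi - lo, 1)
            t.loc[grp["sample_id"]] = (grp["injection_order"].to_numpy() - lo) / span
        return t

    def preceding_qc(self) -> dict[str, str | None]:
        """For each blank, the sample_id of the closest earlier QC injection."""
        out: dict[str, str | None] = {}
        last_qc: str | None = None
        for _, row in self.records.iterrows():
            if row["sample_type"] == "qc":
                last_qc = row["sample_id"]
            elif row["sample_type"] == "blank":
                out[row["sample_id"]] = last_qc
        return out

    def write_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def read_csv(
        cls, path: str | Path, n_batches: int | None = None,
        qc_interval: int = 10, blank_interval: int = 10,
    ) -> "InjectionPlan":
        rec = pd.read_csv(path, dtype={"duplicate_of": str}, keep_default_na=False)
        rec["batch"] = rec["batch"].astype(int)
        rec["injection_order"] = rec["injection_order"].astype(int)
        rec["duplicate_of"] = rec["duplicate_of"].fillna("")
        return cls(
            records=rec,
            n_batches=n_batches or int(rec["batch"].max()),
            qc_interval=qc_interval,
            blank_interval=blank_interval,
        )


def build_injection_sequence(
    n_study: int,
    n_batches: int = 4,
    qc_interval: int = 10,
    blank_interval: int = 10,
    n_duplicate_pairs: int = 20,
    seed: int = 0,
) -> InjectionPlan:
    """Build a randomized, QC-bracketed injection sequence.

    ``n_study`` counts all study injections including the repeats of the
    ``n_duplicate_pairs`` replicated samples; the repeat carries a
    ``duplicate_of`` link to its source.  Study samples are shuffled
    reproducibly from ``seed`` before being chunked into QC blocks.
    """
    if n_duplicate_pairs < 0 or n_study <= 0:
        raise ValueError("n_study must be positive and n_duplicate_pairs >= 0")
    if 2 * n_duplicate_pairs > n_study:
        raise ValueError(
            f"{n_duplicate_pairs} duplicate pairs need {2 * n_duplicate_pairs} "
            f"study injections but only {n_study} are available"
        )
    if n_batches < 1 or qc_interval < 1 or blank_interval < 1:
        raise ValueError("n_batches and intervals must be >= 1")
    n_blocks = math.ceil(n_study / qc_interval)
    if n_blocks < n_batches:
        raise ValueError(
            f"{n_study} study samples form only {n_blocks} QC blocks, "
            f"fewer than {n_batches} batches"
        )

    rng = _rng(seed, _STREAM_PLAN)
    n_subjects = n_study - n_duplicate_pairs
    subjects = [f"S{i:04d}" for i in range(1, n_subjects + 1)]
    entries: list[tuple[str, str]] = [(sid, "") for sid in subjects]
    if n_duplicate_pairs:
        dup_sources = rng.choice(n_subjects, size=n_duplicate_pairs, replace=False)
        entries += [(f"{subjects[j]}-R", subjects[j]) for j in sorted(dup_sources)]
    order_perm = rng.permutation(len(entries))
    entries = [entries[i] for i in order_perm]

    blocks = [entries[i : i + qc_interval] for i in range(0, len(entries), qc_interval)]
    blocks_per_batch = [len(part) for part in np.array_split(np.arange(n_blocks), n_batches)]

    rows: list[dict] = []
    order = 0
    qc_n = blank_n = 0
    study_since_blank = 0
    block_iter = iter(blocks)
    for batch, n_in_batch in enumerate(blocks_per_batch, start=1):
        for _ in range(n_in_batch):
            block = next(block_iter)
            for sample_id, dup_of in block:
                order += 1
                rows.append(
                    dict(
                        sample_id=sample_id,
                        sample_type="study",
                        batch=batch,
                        injection_order=order,
                        duplicate_of=dup_of,
                    )
                )
            study_since_blank += len(block)
            order += 1
            qc_n += 1
            rows.append(
                dict(
                    sample_id=f"QC{qc_n:03d}",
                    sample_type="qc",
                    batch=batch,
                    injection_order=order,
                    duplicate_of="",
                )
            )
            if study_since_blank >= blank_interval:
                study_since_blank -= blank_interval
                order += 1
                blank_n += 1
                rows.append(
                    dict(
                        sample_id=f"B{blank_n:03d}",
                        sample_type="blank",
                        batch=batch,
                        injection_order=order,
                        duplicate_of="",
                    )
                )
    records = pd.DataFrame(rows)
    return InjectionPlan(
        records=records,
        n_batches=n_batches,
        qc_interval=qc_interval,
        blank_interval=blank_interval,
    )


# ---------------------------------------------------------------------------
# Synthetic target database
# ---------------------------------------------------------------------------

_POS_PRIMARY = {"TG": "[M+NH4]+", "other": "[M+H]+"}


def make_synthetic_database(
    n_lipids: int = 30,
    n_internal_standards: int = 5,
    dual_mode_fraction: float = 0.35,
    second_adduct_fraction: float = 0.4,
    unknown_fraction: float = 0.2,
    seed: int = 0,
) -> IonDatabase:
    """Generate a plausible target-ion database.

    Roughly half of the known lipids are triacylglycerols whose m/z values
    come from real formula arithmetic; the rest (and the known unknowns)
    carry random m/z values in the lipid range.  A ``dual_mode_fraction`` of
    lipids appears in both polarities with correlated signals downstream, a
    ``second_adduct_fraction`` carries an extra adduct per mode, and each mode
    gets ``n_internal_standards`` internal standards with retention times
    spread across the gradient (required for the quadratic recalibration).
    """
    if n_internal_standards < 3:
        raise ValueError("need at least 3 internal standards per mode")
    rng = _rng(seed, _STREAM_DB)
    ions: list[TargetIon] = []

    def _rand_inchikey() -> str:
        letters = rng.integers(0, 26, size=14)
        return "".join(chr(ord("A") + int(c)) for c in letters) + "-SYNTHETICSAMN"

    for i in range(1, n_lipids + 1):
        lipid_id = f"L{i:04d}"
        rt = float(np.round(rng.uniform(1.5, 13.5), 3))
        is_unknown = rng.random() < unknown_fraction
        dual = rng.random() < dual_mode_fraction
        is_tg = (not is_unknown) and rng.random() < 0.5
        if is_tg:
            carbons = int(rng.integers(20, 31)) * 2  # 40..60 even
            dbs = int(rng.integers(0, 9))
            name = f"TG({carbons}:{dbs})"
            f = tg_formula(carbons, dbs)
            pos_mz = {
                "[M+NH4]+": display_mz(adduct_mz(f, "[M+NH4]+")),
                "[M+Na]+": display_mz(adduct_mz(f, "[M+Na]+")),
            }
            neg_mz = {
                "[M-H]-": display_mz(adduct_mz(f, "[M-H]-")),
                "[M+OAc]-": display_mz(adduct_mz(f, "[M+OAc]-")),
            }
        else:
            base = float(np.round(rng.uniform(250.0, 1100.0), 4))
            name = (
                f"unknown_{i:04d}@{rt:.2f}"
                if is_unknown
                else f"PC({int(rng.integers(30, 41))}:{int(rng.integers(0, 7))})"
            )
            pos_mz = {
                "[M+H]+": display_mz(base + 1.0073),
                "[M+Na]+": display_mz(base + 22.9892),
            }
            neg_mz = {
                "[M-H]-": display_mz(base - 1.0073),
                "[M+OAc]-": display_mz(base + 59.0139),
            }
        inchikey = "" if is_unknown else _rand_inchikey()
        modes: list[str] = ["positive", "negative"] if dual else (
            ["positive"] if rng.random() < 0.55 else ["negative"]
        )
        for mode in modes:
            table = pos_mz if mode == "positive" else neg_mz
            adducts = list(table)
            n_adducts = 2 if rng.random() < second_adduct_fraction else 1
            for adduct in adducts[:n_adducts]:
                short = adduct.strip("[]+-").replace("M", "").strip("+-")
                ion_id = f"{lipid_id}_{'p' if mode == 'positive' else 'n'}_{short.strip('+')}"
                ions.append(
                    TargetIon(
                        ion_id=ion_id,
                        lipid_id=lipid_id,
                        name=name,
                        mode=mode,
                        adduct=adduct,
                        mz=table[adduct],
                        expected_rt=rt,
                        inchikey=inchikey,
                        is_internal_standard=False,
                        is_known=not is_unknown,
                    )
                )

    std_rts = np.linspace(2.0, 13.0, n_internal_standards)
    for mode in ("positive", "negative"):
        tag = "p" if mode == "positive" else "n"
        for k in range(n_internal_standards):
            rt = float(np.round(std_rts[k] + rng.uniform(-0.2, 0.2), 3))
            lipid_id = f"IS{tag.upper()}{k + 1:02d}"
            adduct = "[M+H]+" if mode == "positive" else "[M-H]-"
            ions.append(
                TargetIon(
                    ion_id=f"{lipid_id}_{tag}",
                    lipid_id=lipid_id,
                    name=f"ISTD {tag}{k + 1} (d-labeled)",
                    mode=mode,
                    adduct=adduct,
                    mz=float(np.round(rng.uniform(250.0, 900.0), 4)),
                    expected_rt=rt,
                    inchikey=_rand_inchikey(),
                    is_internal_standard=True,
                    is_known=True,
                )
            )
    return IonDatabase(ions)


# ---------------------------------------------------------------------------
# Ground truth and EIC simulation
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class GroundTruth:
    """True generative state of a simulated run.

    ``concentrations`` holds the true level of every lipid in every non-blank
    injection (a.u.); the QC pool level of a lipid is identical across all QC
    injections and duplicate pairs share their source sample's row.
    ``drift`` stores, per (ion, batch), the multiplicative response curve as
    a polynomial g(t) = g0 + g1*t + g2*t**2 in the normalized within-batch
    position t.  ``rt_coeffs`` holds the per-sample quadratic retention-time
    distortion (a, b, c).
    """

    concentrations: pd.DataFrame  # index sample_id (non-blank), columns lipid_id
    response: pd.Series  # index ion_id
    drift: pd.DataFrame  # index (ion_id, batch), columns g0, g1, g2
    rt_coeffs: pd.DataFrame  # index sample_id, columns a, b, c

    def drift_factor(self, ion_id: str, batch: int, t: float | np.ndarray):
        g0, g1, g2 = self.drift.loc[(ion_id, int(batch))]
        return g0 + g1 * np.asarray(t, dtype=float) + g2 * np.asarray(t, dtype=float) ** 2

    def distorted_rt(self, sample_id: str, expected_rt: float | np.ndarray):
        a, b, c = self.rt_coeffs.loc[sample_id]
        e = np.asarray(expected_rt, dtype=float)
        return a * e**2 + b * e + c


def simulate_true_concentrations(
    db: IonDatabase,
    plan: InjectionPlan,
    params: RunParameters,
    seed: int | None = None,
) -> GroundTruth:
    """Draw per-lipid true concentrations, responses, drift and RT distortion.

    Study-sample levels are lognormal around a per-lipid mean; the QC pool is
    fixed at that mean; internal standards are spiked at a constant level in
    every non-blank sample; all adducts (and both polarities) of one lipid
    share its concentration, scaled by fixed per-ion response factors.
    """
    seed = params.seed if seed is None else seed
    rng_conc = _rng(seed, _STREAM_CONC)
    rng_resp = _rng(seed, _STREAM_RESP)
    rng_drift = _rng(seed, _STREAM_DRIFT)
    rng_rt = _rng(seed, _STREAM_RT)

    groups = db.lipid_groups()
    lipid_ids = list(groups)
    is_standard = {lid: ions[0].is_internal_standard for lid, ions in groups.items()}
    lo, hi = params.mean_log10_height
    lipid_mean = pd.Series(
        10.0 ** rng_conc.uniform(lo, hi, size=len(lipid_ids)), index=lipid_ids
    )

    rec = plan.records
    nonblank = rec[rec["sample_type"] != "blank"]
    sigma_bio = (
        math.sqrt(math.log(1.0 + params.biological_cv**2))
        if params.biological_cv > 0
        else 0.0
    )
    conc = np.empty((len(nonblank), len(lipid_ids)))
    bio = (
        np.exp(rng_conc.normal(-0.5 * sigma_bio**2, sigma_bio, conc.shape))
        if sigma_bio > 0
        else np.ones_like(conc)
    )
    for j, lid in enumerate(lipid_ids):
        base = lipid_mean[lid]
        if is_standard[lid]:
            conc[:, j] = base  # constant spike everywhere
        else:
            is_qc = (nonblank["sample_type"] == "qc").to_numpy()
            conc[:, j] = np.where(is_qc, base, base * bio[:, j])
    concentrations = pd.DataFrame(
        conc, index=nonblank["sample_id"].to_numpy(), columns=lipid_ids
    )
    # duplicate pairs share the true sample
    for source, repeat in plan.duplicate_pairs:
        concentrations.loc[repeat] = concentrations.loc[source]

    response = pd.Series(
        rng_resp.uniform(params.response_low, 1.0, size=len(db)), index=db.ion_ids
    )

    amp = params.drift_amplitude
    drift_rows = []
    for ion_id in db.ion_ids:
        for batch in range(1, plan.n_batches + 1):
            scale = (
                math.exp(rng_drift.normal(0.0, params.batch_scale_sigma))
                if params.batch_scale_sigma > 0
                else 1.0
            )
            slope = rng_drift.uniform(-1.0, 1.0)
            curv = (
                rng_drift.uniform(-1.0, 1.0)
                if params.drift_shape == "quadratic"
                else 0.0
            )
            # g(t) = scale * (1 + amp*(slope*(t-1/2) + curv*((t-1/2)^2 - 1/12)))
            g0 = scale * (1.0 + amp * (-0.5 * slope + curv * (0.25 - 1.0 / 12.0)))
            g1 = scale * amp * (slope - curv)
            g2 = scale * amp * curv
            drift_rows.append((ion_id, batch, g0, g1, g2))
    drift = pd.DataFrame(
        drift_rows, columns=["ion_id", "batch", "g0", "g1", "g2"]
    ).set_index(["ion_id", "batch"])

    n_samples = len(rec)
    rt_coeffs = pd.DataFrame(
        {
            "a": rng_rt.normal(0.0, params.rt_quad_sd, n_samples),
            "b": rng_rt.normal(1.0, params.rt_slope_sd, n_samples),
            "c": rng_rt.normal(0.0, params.rt_shift_sd, n_samples),
        },
        index=rec["sample_id"].to_numpy(),
    )
    return GroundTruth(
        concentrations=concentrations,
        response=response,
        drift=drift,
        rt_coeffs=rt_coeffs,
    )


@dataclasses.dataclass
class EICSet:
    """Per-sample, per-ion extracted-ion chromatograms on fixed RT grids.

    Each target ion has its own grid spanning expected RT +/- `span` minutes;
    ``traces[ion_id]`` is an (n_samples, n_grid) intensity array in plan
    order.  ``heights`` and ``true_apex_rt`` record the realized generative
    peak heights (noise included, baseline excluded) and distorted apex
    positions for verification against downstream estimates.
    """

    samples: list[str]
    ions: list[str]
    grids: dict[str, np.ndarray]
    traces: dict[str, np.ndarray]
    heights: pd.DataFrame | None = None
    true_apex_rt: pd.DataFrame | None = None

    def trace(self, sample_id: str, ion_id: str) -> tuple[np.ndarray, np.ndarray]:
        i = self.samples.index(sample_id)
        return self.grids[ion_id], self.traces[ion_id][i]

    def sample_table(self, sample_id: str) -> pd.DataFrame:
        """Wide per-sample table on the union RT grid (absent points are NaN)."""
        i = self.samples.index(sample_id)
        union = np.unique(np.concatenate([np.round(g, 6) for g in self.grids.values()]))
        data = {}
        for ion_id in self.ions:
            col = np.full(union.shape, np.nan)
            idx = np.searchsorted(union, np.round(self.grids[ion_id], 6))
            col[idx] = self.traces[ion_id][i]
            data[ion_id] = col
        return pd.DataFrame(data, index=pd.Index(union, name="rt_min"))


def simulate_eics(
    db: IonDatabase,
    plan: InjectionPlan,
    truth: GroundTruth,
    params: RunParameters,
    seed: int | None = None,
    span: float = 1.0,
) -> EICSet:
    """Render Gaussian chromatographic peaks into per-ion EIC grids.

    Peak height = concentration x response x batch drift x lognormal noise;
    the apex sits at the sample's distorted retention time; a constant
    baseline with Gaussian point noise is added and intensities are clipped
    at zero.  Blanks contain ``carryover_fraction`` of the immediately
    preceding QC's realized peak height, plus baseline.
    """
    seed = params.seed if seed is None else seed
    rng_noise = _rng(seed, _STREAM_NOISE)
    rng_base = _rng(seed, _STREAM_BASELINE)

    rec = plan.records
    samples = list(rec["sample_id"])
    n_samples = len(samples)
    sample_type = rec["sample_type"].to_numpy()
    batch = rec["batch"].to_numpy()
    t_pos = plan.batch_position().reindex(samples).to_numpy()
    prev_qc = plan.preceding_qc()
    sample_index = {s: i for i, s in enumerate(samples)}

    sigma = (
        math.sqrt(math.log(1.0 + params.noise_cv**2)) if params.noise_cv > 0 else 0.0
    )
    noise = (
        np.exp(rng_noise.normal(-0.5 * sigma**2, sigma, (n_samples, len(db))))
        if sigma > 0
        else np.ones((n_samples, len(db)))
    )

    n_half = int(round(span / params.rt_grid_step))
    rel_grid = np.arange(-n_half, n_half + 1) * params.rt_grid_step

    a = truth.rt_coeffs["a"].reindex(samples).to_numpy()
    b = truth.rt_coeffs["b"].reindex(samples).to_numpy()
    c = truth.rt_coeffs["c"].reindex(samples).to_numpy()

    grids: dict[str, np.ndarray] = {}
    traces: dict[str, np.ndarray] = {}
    heights = np.zeros((n_samples, len(db)))
    apex_true = np.zeros((n_samples, len(db)))

    for j, ion in enumerate(db):
        e = ion.expected_rt
        grid = e + rel_grid
        rt_obs = a * e * e + b * e + c
        shift = np.abs(rt_obs - e)
        if np.any(shift > span):
            worst = samples[int(np.argmax(shift))]
            raise SimulationError(
                f"distorted retention time of ion {ion.ion_id!r} falls outside "
                f"the EIC span for sample {worst!r}"
            )
        h = np.zeros(n_samples)
        nonblank_mask = sample_type != "blank"
        conc = truth.concentrations[ion.lipid_id].reindex(
            rec.loc[nonblank_mask, "sample_id"]
        ).to_numpy()
        g = np.empty(nonblank_mask.sum())
        nb_batches = batch[nonblank_mask]
        nb_t = t_pos[nonblank_mask]
        for bb in np.unique(nb_batches):
            m = nb_batches == bb
            g[m] = truth.drift_factor(ion.ion_id, int(bb), nb_t[m])
        h[nonblank_mask] = (
            conc * truth.response[ion.ion_id] * g * noise[nonblank_mask, j]
        )
        # carryover into blanks from the immediately preceding QC
        for i, s in enumerate(samples):
            if sample_type[i] == "blank":
                src = prev_qc.get(s)
                if src is not None and params.carryover_fraction > 0:
                    h[i] = params.carryover_fraction * h[sample_index[src]]
        peak = h[:, None] * np.exp(
            -0.5 * ((grid[None, :] - rt_obs[:, None]) / params.peak_width_sd) ** 2
        )
        y = peak + params.baseline_level
        if params.baseline_noise > 0:
            y = y + rng_base.normal(0.0, params.baseline_noise, peak.shape)
        traces[ion.ion_id] = np.maximum(y, 0.0)
        grids[ion.ion_id] = grid
        heights[:, j] = h
        apex_true[:, j] = rt_obs

    return EICSet(
        samples=samples,
        ions=db.ion_ids,
        grids=grids,
        traces=traces,
        heights=pd.DataFrame(heights, index=samples, columns=db.ion_ids),
        true_apex_rt=pd.DataFrame(apex_true, index=samples, columns=db.ion_ids),
    )


def simulate_run(
    db: IonDatabase, plan: InjectionPlan, params: RunParameters, seed: int | None = None
) -> tuple[GroundTruth, EICSet]:
    truth = simulate_true_concentrations(db, plan, params, seed=seed)
    eics = simulate_eics(db, plan, truth, params, seed=seed)
    return truth, eics


# ---------------------------------------------------------------------------
# On-disk run format
# ---------------------------------------------------------------------------


def write_run(
    plan: InjectionPlan,
    eics: EICSet,
    db: IonDatabase,
    out_dir: str | Path,
    truth: GroundTruth | None = None,
    overwrite: bool = False,
) -> Path:
    """Write a run directory: plan.csv, database.csv, eics/<sample>.csv and,
    when ground truth is supplied, truth.csv (long format)."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} exists and is not empty (pass overwrite=True)")
    (out / "eics").mkdir(parents=True, exist_ok=True)
    plan.write_csv(out / "plan.csv")
    db.write_csv(out / "database.csv")
    if truth is not None:
        _write_truth(truth, out / "truth.csv")
    for sample_id in eics.samples:
        eics.sample_table(sample_id).to_csv(out / "eics" / f"{sample_id}.csv")
    return out


def _write_truth(truth: GroundTruth, path: Path) -> None:
    rows: list[tuple[str, str, str, float]] = []
    for sample_id, row in truth.concentrations.iterrows():
        for lipid_id, v in row.items():
            rows.append(("concentration", str(sample_id), str(lipid_id), float(v)))
    for ion_id, v in truth.response.items():
        rows.append(("response", str(ion_id), "", float(v)))
    for (ion_id, batch), row in truth.drift.iterrows():
        for field in ("g0", "g1", "g2"):
            rows.append(("drift", str(ion_id), f"{batch}:{field}", float(row[field])))
    for sample_id, row in truth.rt_coeffs.iterrows():
        for field in ("a", "b", "c"):
            rows.append(("rt", str(sample_id), field, float(row[field])))
    pd.DataFrame(rows, columns=["table", "key1", "key2", "value"]).to_csv(
        path, index=False
    )


def _read_truth(path: Path) -> GroundTruth:
    long = pd.read_csv(path, dtype={"key1": str, "key2": str},
                       keep_default_na=False, float_precision="round_trip")
    conc = long[long["table"] == "concentration"].pivot(
        index="key1", columns="key2", values="value"
    )
    conc.index.name = None
    conc.columns.name = None
    resp = long[long["table"] == "response"].set_index("key1")["value"]
    resp.index.name = None
    drift_rows = long[long["table"] == "drift"].copy()
    drift_rows[["batch", "field"]] = drift_rows["key2"].str.split(":", expand=True)
    drift = (
        drift_rows.pivot(index=["key1", "batch"], columns="field", values="value")
        .rename_axis(index=["ion_id", "batch"])[["g0", "g1", "g2"]]
    )
    drift.index = pd.MultiIndex.from_tuples(
        [(i, int(b)) for i, b in drift.index], names=["ion_id", "batch"]
    )
    rt_rows = long[long["table"] == "rt"]
    rt = rt_rows.pivot(index="key1", columns="key2", values="value")[["a", "b", "c"]]
    rt.index.name = None
    rt.columns.name = None
    return GroundTruth(
        concentrations=conc, response=resp, drift=drift, rt_coeffs=rt
    )


def read_run(
    run_dir: str | Path,
) -> tuple[IonDatabase, InjectionPlan, EICSet, GroundTruth | None]:
    """Reload a run directory written by :func:`write_run`."""
    src = Path(run_dir)
    db = load_ion_database(src / "database.csv")
    plan = InjectionPlan.read_csv(src / "plan.csv")
    truth = _read_truth(src / "truth.csv") if (src / "truth.csv").exists() else None

    samples = plan.sample_ids
    grids: dict[str, np.ndarray] = {}
    per_ion: dict[str, list[np.ndarray]] = {ion_id: [] for ion_id in db.ion_ids}
    for sample_id in samples:
        table = pd.read_csv(
            src / "eics" / f"{sample_id}.csv", index_col="rt_min",
            float_precision="round_trip",
        )
        for ion_id in db.ion_ids:
            col = table[ion_id]
            present = col.notna()
            grid = table.index.to_numpy()[present.to_numpy()]
            if ion_id not in grids:
                grids[ion_id] = grid
            elif not np.allclose(grids[ion_id], grid):
                raise ValueError(f"inconsistent RT grid for ion {ion_id!r}")
            per_ion[ion_id].append(col.to_numpy()[present.to_numpy()])
    traces = {ion_id: np.vstack(arrs) for ion_id, arrs in per_ion.items()}
    eics = EICSet(samples=samples, ions=db.ion_ids, grids=grids, traces=traces)
    return db, plan, eics, truth
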