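"""The samples x target-ions peak-height table and its CSV dialect.

A :class:`FeatureMatrix` bundles the peak-height values with the sample
annotations (type, batch, injection order, duplicate links) and the ion
annotations joined from the target database, plus a provenance string that
records the normalization state ("raw", "drift_corrected", ...).  Missing
measurements are explicit NaN markers, never zeros: zero is a legitimate
intensity.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd

SAMPLE_COLUMNS = ("sample_type", "batch", "injection_order", "duplicate_of")


@dataclasses.dataclass
class FeatureMatrix:
    values: pd.DataFrame  # index: sample_id, columns: ion_id
    samples: pd.DataFrame  # index: sample_id; sample_type, batch, injection_order, duplicate_of
    ions: pd.DataFrame  # index: ion_id; database annotations
    provenance: str = "raw"
    snr: pd.DataFrame | None = None
    apex_rt: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.samples.index):
            raise ValueError("values and sample annotations disagree on sample ids")
        unknown = [c for c in self.values.columns if c not in self.ions.index]
        if unknown:
            raise ValueError(f"ions missing from annotations: {unknown[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def ion_ids(self) -> list[str]:
        return list(self.values.columns)

    def mask(self, sample_type: str) -> pd.Series:
        return self.samples["sample_type"] == sample_type

    def qc_values(self) -> pd.DataFrame:
        return self.values.loc[self.mask("qc")]

    def nonblank_values(self) -> pd.DataFrame:
        return self.values.loc[~self.mask("blank")]

    def duplicate_pairs(self) -> list[tuple[str, str]]:
        """(original, repeat) sample-id pairs from the annotations."""
        pairs = []
        dup = self.samples["duplicate_of"]
        for sample_id, source in dup.items():
            if isinstance(source, str) and source:
                pairs.append((source, sample_id))
        return pairs

    def copy_with(
        self,
        values: pd.DataFrame | None = None,
        provenance: str | None = None,
    ) -> "FeatureMatrix":
        return FeatureMatrix(
            values=(self.values if values is None else values).copy(),
            samples=self.samples.copy(),
            ions=self.ions.copy(),
            provenance=self.provenance if provenance is None else provenance,
            snr=None if self.snr is None else self.snr.copy(),
            apex_rt=None if self.apex_rt is None else self.apex_rt.copy(),
        )

    # -- CSV dialect --------------------------------------------------------
    # values.csv: "# provenance: <state>" comment line, then sample_id + one
    # column per ion.  samples.csv / ions.csv are annotation sidecars.

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "values.csv", "w") as fh:
            fh.write(f"# provenance: {self.provenance}\n")
            self.values.rename_axis("sample_id").to_csv(fh)
        self.samples.rename_axis("sample_id").to_csv(out / "samples.csv")
        self.ions.rename_axis("ion_id").to_csv(out / "ions.csv", index=False)
        if self.snr is not None:
            self.snr.rename_axis("sample_id").to_csv(out / "snr.csv")
        if self.apex_rt is not None:
            self.apex_rt.rename_axis("sample_id").to_csv(out / "apex_rt.csv")
        return out

    @classmethod
    def read(cls, in_dir: str | Path) -> "FeatureMatrix":
        src = Path(in_dir)
        provenance = "raw"
        with open(src / "values.csv") as fh:
            first = fh.readline()
            if first.startswith("# provenance:"):
                provenance = first.split(":", 1)[1].strip()
        values = pd.read_csv(
            src / "values.csv", comment="#", index_col="sample_id",
            float_precision="round_trip",
        )
        samples = pd.read_csv(
            src / "samples.csv", index_col="sample_id", keep_default_na=False
        )
        samples["batch"] = samples["batch"].astype(int)
        samples["injection_order"] = samples["injection_order"].astype(int)
        ions = pd.read_csv(src / "ions.csv", keep_default_na=False)
        ions = ions.set_index("ion_id", drop=False)
        for col in ("mz", "expected_rt"):
            ions[col] = ions[col].astype(float)
        for col in ("is_internal_standard", "is_known"):
            ions[col] = ions[col].map(
                lambda v: str(v).strip().lower() in {"true", "t", "1", "yes"}
            )
        snr = apex = None
        if (src / "snr.csv").exists():
            snr = pd.read_csv(src / "snr.csv", index_col="sample_id",
                              float_precision="round_trip")
        if (src / "apex_rt.csv").exists():
            apex = pd.read_csv(src / "apex_rt.csv", index_col="sample_id",
                               float_precision="round_trip")
        return cls(
            values=values,
            samples=samples,
            ions=ions,
            provenance=provenance,
            snr=snr,
            apex_rt=apex,
        )
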