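"""Shared in-memory containers for the methylation pipeline.

Beta values live in probes x samples :class:`pandas.DataFrame` objects,
paired with an identically shaped detection p-value frame. The sample
sheet and probe annotation are plain DataFrames with documented columns
(see :mod:`ewasmeta.synthio` and :mod:`ewasmeta.probeset`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sample roles carried on the sample sheet. Only ``study`` samples enter
#: association models; the others are assay controls.
SAMPLE_ROLES = ("study", "cephrep", "positive_bsm", "negative_bsm", "duplicate")

#: Fixed category levels for the case-control model covariates. Each
#: categorical covariate carries an explicit ``missing`` level rather than
#: dropping samples.
PARITY_LEVELS = (
    "nulliparous",
    "1-2_le20",
    "1-2_gt20",
    "3plus_le20",
    "3plus_gt20",
    "missing",
)
ALCOHOL_LEVELS = ("never", "former", "current", "missing")
SMOKING_LEVELS = ("never_former", "current", "missing")
STATE_LEVELS = ("MN", "non-MN")
STAGE_LEVELS = ("I_II", "III_IV")
ASCITES_LEVELS = ("no", "yes", "missing")
DEBULKING_LEVELS = ("optimal", "suboptimal", "missing")


class BetaMatrixError(ValueError):
    """Raised when beta/detection frames are inconsistent."""


@dataclass
class BetaMatrix:
    """Probes x samples methylation fractions with detection p-values.

    Parameters
    ----------
    beta
        Methylation beta values in ``[0, 1]`` (NaN allowed for missing
        entries), probes as the index, samples as columns.
    detp
        Detection p-values aligned entry-by-entry with ``beta``.
    """

    beta: pd.DataFrame
    detp: pd.DataFrame

    def __post_init__(self) -> None:
        if self.beta.shape != self.detp.shape:
            raise BetaMatrixError(
                f"beta {self.beta.shape} and detp {self.detp.shape} differ in shape"
            )
        if not self.beta.index.equals(self.detp.index) or not self.beta.columns.equals(
            self.detp.columns
        ):
            raise BetaMatrixError("beta and detp must share probe and sample labels")
        if self.beta.index.has_duplicates:
            raise BetaMatrixError("duplicate probe ids")
        if self.beta.columns.has_duplicates:
            raise BetaMatrixError("duplicate sample ids")
        vals = self.beta.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise BetaMatrixError("beta values outside [0, 1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.columns

    def subset_samples(self, sample_ids) -> "BetaMatrix":
        cols = [s for s in sample_ids if s in self.beta.columns]
        return BetaMatrix(self.beta[cols], self.detp[cols])

    def subset_probes(self, probe_ids) -> "BetaMatrix":
        idx = self.beta.index.intersection(pd.Index(probe_ids))
        return BetaMatrix(self.beta.loc[idx], self.detp.loc[idx])


@dataclass
class QCReport:
    """Outcome of probe- and sample-level quality control.

    ``excluded_probes`` / ``excluded_samples`` carry one row per excluded
    id with its primary reason (the first failing rule in the documented
    rule order). ``concordance`` holds replicate-agreement summaries.
    """

    excluded_probes: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["probe_id", "reason"])
    )
    excluded_samples: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["sample_id", "reason"])
    )
    concordance: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["group", "n_members", "min_pairwise_r", "mean_pairwise_r", "icc"]
        )
    )

    @property
    def excluded_probe_ids(self) -> set:
        return set(self.excluded_probes["probe_id"])

    @property
    def excluded_sample_ids(self) -> set:
        return set(self.excluded_samples["sample_id"])
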