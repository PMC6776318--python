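"""Result containers shared by the association tests.

Every region-level test in the package (collapsing GLM tests and the
SKAT family) reports a :class:`TestResult`.  A result carries an explicit
``status`` so that degenerate replicates (no predictor variation) and
failed fits are flagged rather than silently dropped or given arbitrary
p-values; the evaluation module excludes them from rejection-rate
denominators and reports their count.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Optional

import pandas as pd

#: valid result statuses
STATUS_OK = "ok"
STATUS_FAILED = "failed"
STATUS_DEGENERATE = "degenerate"


@dataclass
class TestResult:
    """Outcome of a single region-level association test.

    Attributes
    ----------
    method : str
        Display label, e.g. ``"SKAT"`` or ``"Poisson-sum"``.
    statistic : float or None
        Test statistic (Wald z, LRT/score chi-square, SKAT Q, or the
        minimum per-rho p for SKAT-O).
    p_value : float or None
        Present exactly when ``status == "ok"``.
    test_type : str or None
        ``"wald"``, ``"score"``, ``"lrt"`` for GLM tests; ``None`` for the
        SKAT family.
    status : str
        ``"ok"``, ``"failed"`` or ``"degenerate"``.
    """

    method: str
    statistic: Optional[float] = None
    p_value: Optional[float] = None
    test_type: Optional[str] = None
    status: str = STATUS_OK

    def __post_init__(self) -> None:
        if self.status not in (STATUS_OK, STATUS_FAILED, STATUS_DEGENERATE):
            raise ValueError(f"unknown status {self.status!r}")
        if (self.p_value is not None) != (self.status == STATUS_OK):
            raise ValueError("p_value must be present exactly when status is 'ok'")
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value out of [0, 1]: {self.p_value}")


@dataclass
class ResultsRecord:
    """A Table-1 style output row for a real-data run."""

    gene: str
    method: str
    statistic: Optional[float]
    p_value: Optional[float]
    n_variants_tested: int
    status: str = STATUS_OK

    def __post_init__(self) -> None:
        if self.status == STATUS_OK and self.n_variants_tested < 1:
            raise ValueError("n_variants_tested must be >= 1 for an ok record")


def results_to_frame(records: Iterable[TestResult | ResultsRecord]) -> pd.DataFrame:
    """Convert test results to a tidy DataFrame (shared results schema)."""
    rows = [asdict(r) for r in records]
    if not rows:
        raise ValueError("no records to convert")
    return pd.DataFrame(rows)
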