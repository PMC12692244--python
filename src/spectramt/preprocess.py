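"""Standard Normal Variate (SNV) preprocessing.

SNV standardises each spectrum to zero mean and unit variance, removing the
multiplicative scatter and additive baseline-offset artefacts caused by
particle size, surface roughness and optical-path variation.  It is the only
preprocessing applied before band selection and modelling.
"""

from __future__ import annotations

import numpy as np

from .synthspec import SpectraTable

__all__ = ["snv", "snv_table", "SNV_DDOF"]

# Sample (N-1) standard deviation; the SNV literature is split on the
# denominator, so it is a single switchable constant.
SNV_DDOF = 1


def snv(spectrum: np.ndarray, source_id: str | None = None,
        ddof: int = SNV_DDOF) -> np.ndarray:
    """(x - mean(x)) / sd(x) for one spectrum.

    Raises ``ValueError`` (naming ``source_id`` when given) for spectra of
    length < 2 or zero variance, where the transform is undefined.
    """
    x = np.asarray(spectrum, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("SNV needs a 1-D spectrum of length >= 2")
    sd = x.std(ddof=ddof)
    if sd == 0:
        tag = f" (scan {source_id})" if source_id else ""
        raise ValueError(f"zero-variance spectrum{tag}: SNV undefined")
    return (x - x.mean()) / sd


def snv_table(table: SpectraTable, ddof: int = SNV_DDOF) -> SpectraTable:
    """Row-wise SNV over a whole table; labels pass through untouched.

    Per-row failures are aggregated into one error report.
    """
    X = table.X
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=ddof, keepdims=True)
    bad = np.flatnonzero(sd[:, 0] == 0)
    if bad.size:
        ids = table.labels["scan_id"].iloc[bad].tolist()
        raise ValueError(
            f"zero-variance spectra in {bad.size} row(s): {ids[:10]}"
        )
    return SpectraTable(table.labels.copy(), (X - mean) / sd, table.grid)
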