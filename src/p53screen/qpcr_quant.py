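"""Relative-standard-curve quantification of qPCR Ct values.

A dilution series of known relative template amounts is amplified alongside
the samples; ordinary least squares of Ct against log10(quantity) gives the
standard curve.  A sample's Ct is converted back to a relative amount via the
inverse of that line, triplicate reactions are averaged on the quantity
scale, and each target amount is divided by the LMNA reference amount from
the same well-set to give the normalized expression ratio used everywhere
downstream.

Amplification efficiency follows from the slope: a perfect doubling per cycle
gives slope -1/log10(2) = -3.3219 and efficiency E = 10^(-1/slope) - 1 = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientCurveError
from .screen_io import (
    COLUMN_LABELS,
    CONDITIONS,
    REFERENCE_GENE,
    ScreenMatrix,
    condition_label,
)

#: Replicate Ct spread (cycles) above which a well-set is flagged for review.
CT_SD_FLAG_CYCLES = 0.5


@dataclass(frozen=True)
class StandardCurve:
    """Fitted dilution-series regression for one amplicon.

    Attributes
    ----------
    readout : str
        Amplicon (readout or reference gene) the curve belongs to.
    slope : float
        Cycles per log10(quantity); negative for any sensible chemistry.
    intercept : float
        Ct at log10(quantity) = 0.
    r_squared : float
        Coefficient of determination of the fit.
    efficiency : float
        Per-cycle amplification gain, ``10 ** (-1 / slope) - 1``.
    warning : bool
        Set when the fitted slope is non-negative (nonsensical chemistry);
        the curve is still returned so the caller can inspect it.
    """

    readout: str
    slope: float
    intercept: float
    r_squared: float
    efficiency: float
    warning: bool = False


def fit_standard_curve(
    points: Sequence[tuple[float, float]], readout: str = ""
) -> StandardCurve:
    """Fit Ct = intercept + slope * log10(quantity) by ordinary least squares.

    Parameters
    ----------
    points : sequence of (quantity, ct)
        At least 3 points spanning at least 2 distinct quantities; quantities
        are arbitrary relative units > 0.

    Raises
    ------
    InsufficientCurveError
        Fewer than 3 points, a non-positive quantity, or all quantities equal.
    """
    if len(points) < 3:
        raise InsufficientCurveError(
            f"standard curve needs >= 3 points, got {len(points)}"
        )
    q = np.asarray([p[0] for p in points], dtype=float)
    ct = np.asarray([p[1] for p in points], dtype=float)
    if (q <= 0).any():
        raise InsufficientCurveError("dilution quantities must be > 0")
    x = np.log10(q)
    if np.unique(x).size < 2:
        raise InsufficientCurveError("all dilution quantities are equal")

    slope, intercept = np.polyfit(x, ct, 1)
    resid = ct - (intercept + slope * x)
    ss_tot = float(np.sum((ct - ct.mean()) ** 2))
    r_squared = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    warning = slope >= 0
    efficiency = math.nan if warning else 10.0 ** (-1.0 / slope) - 1.0
    return StandardCurve(
        readout=readout,
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r_squared,
        efficiency=efficiency,
        warning=warning,
    )


def relative_quantity(ct: float, curve: StandardCurve) -> float:
    """Invert a standard curve: quantity = 10 ** ((ct - intercept) / slope).

    Strictly decreasing in Ct for any valid (negative-slope) curve.  A missing
    Ct (NaN/None) propagates as NaN rather than raising, so dead wells flow
    through the screen as missing values.
    """
    if curve.slope >= 0:
        raise InsufficientCurveError("cannot quantify against a non-negative slope")
    if ct is None or (isinstance(ct, float) and math.isnan(ct)):
        return math.nan
    return 10.0 ** ((float(ct) - curve.intercept) / curve.slope)


def aggregate_replicates(
    cts: Iterable[float], curve: StandardCurve
) -> tuple[float, bool, str]:
    """Collapse replicate Ct values for one gene x readout x treatment.

    Each replicate Ct is converted to a quantity and the quantities averaged
    (the relative-standard-curve method reports on the quantity scale, so the
    average is taken there, not on Ct).

    Returns
    -------
    (quantity, qc_flag, reason)
        ``qc_flag`` is True when replicate Ct SD exceeds
        :data:`CT_SD_FLAG_CYCLES` cycles or fewer than 2 replicates are
        present.  When all replicates are missing, quantity is NaN and
        ``reason`` says why.
    """
    ct_arr = np.asarray(list(cts), dtype=float)
    present = ct_arr[~np.isnan(ct_arr)]
    if present.size == 0:
        return math.nan, True, "all replicates missing"
    quantities = np.array([relative_quantity(c, curve) for c in present])
    flag = False
    reason = ""
    if present.size < 2:
        flag, reason = True, "fewer than 2 replicates"
    elif present.size >= 2 and float(np.std(present, ddof=1)) > CT_SD_FLAG_CYCLES:
        flag, reason = True, "replicate Ct SD > 0.5 cycles"
    return float(np.mean(quantities)), flag, reason


def normalize_to_reference(target_quantity: float, reference_quantity: float):
    """Expression ratio target/reference.

    Returns ``(value, reason)``.  A missing or non-positive reference yields a
    missing value with a reason code instead of an exception: knockdowns that
    kill the well produce no reference signal, and the screen must carry on.
    """
    if target_quantity is None or (
        isinstance(target_quantity, float) and math.isnan(target_quantity)
    ):
        return math.nan, "target missing"
    if (
        reference_quantity is None
        or (isinstance(reference_quantity, float) and math.isnan(reference_quantity))
        or reference_quantity <= 0
    ):
        return math.nan, "reference missing or non-positive"
    return float(target_quantity) / float(reference_quantity), ""


# ---------------------------------------------------------------------------
# whole-table pipeline
# ---------------------------------------------------------------------------


def fit_curves_from_standards(ct_records: pd.DataFrame) -> dict[str, StandardCurve]:
    """Fit one standard curve per amplicon from rows with role == 'standard'.

    Standard rows must carry a ``quantity`` column (relative dilution units).
    """
    std = ct_records[ct_records["role"] == "standard"]
    if std.empty:
        raise InsufficientCurveError("no standard-curve rows (role == 'standard')")
    if "quantity" not in std.columns:
        raise InsufficientCurveError("standard rows lack a 'quantity' column")
    curves: dict[str, StandardCurve] = {}
    for readout, grp in std.groupby("readout", sort=False):
        pts = list(zip(grp["quantity"].astype(float), grp["ct"].astype(float)))
        curves[readout] = fit_standard_curve(pts, readout=readout)
    return curves


def quantify_screen(
    ct_records: pd.DataFrame,
    curves: Mapping[str, StandardCurve] | None = None,
) -> tuple[ScreenMatrix, pd.DataFrame]:
    """Run the full Ct -> normalized-expression pipeline for a screen.

    Parameters
    ----------
    ct_records : DataFrame
        Long Ct table as returned by
        ``read_screen_table(path, schema="ct_long")``: columns gene, readout,
        treatment, replicate, ct, role (and quantity for standard rows).
        The reference gene LMNA appears as its own readout rows.
    curves : mapping readout -> StandardCurve, optional
        If omitted, fitted from the table's own standard rows.

    Returns
    -------
    (matrix, qc)
        ``matrix`` is the LMNA-normalized :class:`~p53screen.screen_io.ScreenMatrix`;
        ``qc`` is a long DataFrame of per-well-set QC flags and reason codes.
    """
    if curves is None:
        curves = fit_curves_from_standards(ct_records)
    samples = ct_records[ct_records["role"] != "standard"]

    # per gene x readout x treatment: replicate-aggregated quantity
    quantities: dict[tuple[str, str, str], float] = {}
    qc_rows = []
    for (gene, readout, treatment), grp in samples.groupby(
        ["gene", "readout", "treatment"], sort=False
    ):
        curve = curves.get(readout)
        if curve is None:
            raise InsufficientCurveError(f"no standard curve for readout {readout!r}")
        qty, flag, reason = aggregate_replicates(grp["ct"].astype(float), curve)
        quantities[(gene, readout, treatment)] = qty
        if flag:
            qc_rows.append((gene, readout, treatment, reason))

    genes = list(dict.fromkeys(samples["gene"]))
    values = pd.DataFrame(np.nan, index=genes, columns=list(COLUMN_LABELS))
    for gene in genes:
        for readout, treatment in CONDITIONS:
            target = quantities.get((gene, readout, treatment), math.nan)
            reference = quantities.get((gene, REFERENCE_GENE, treatment), math.nan)
            value, reason = normalize_to_reference(target, reference)
            values.at[gene, condition_label(readout, treatment)] = value
            if reason and reason != "target missing":
                qc_rows.append((gene, readout, treatment, reason))

    roles = pd.Series("library", index=genes)
    if "role" in samples.columns:
        roles.update(samples.groupby("gene", sort=False)["role"].first())
    qc = pd.DataFrame(qc_rows, columns=["gene", "readout", "treatment", "reason"])
    return ScreenMatrix(values, roles), qc
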