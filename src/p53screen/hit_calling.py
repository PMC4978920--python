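"""Z-score hit calling, regulator classification and validation.

For each of the six readout-condition columns the standard score
``z = (X - mu) / theta`` is computed, where mu and theta are the mean and
sample standard deviation of the normalized expression values across the
library siRNAs for that column.  Dedicated per-plate control wells are
excluded from mu/theta by default (they repeat on every plate and would bias
the population statistics) but still receive z-scores against the library
statistics — so the TP53 siRNA that is itself part of the library is scored
like any other target.

A knockdown with |z| strictly greater than the threshold (default 2) is a
hit; a value exactly on the boundary lies inside the non-hit window.  The
sign convention: knockdown *lowering* a readout (z below -threshold) marks
the targeted gene as a *positive regulator* of that readout, and vice versa.

Genes are then classified:

* joint          — same-direction hits for CDKN1A and BBC3 in one treatment;
* CDKN1A/BBC3-specific — a hit for that readout in a treatment where the
  partner readout is not a hit, for genes that are not joint in any
  treatment;
* TP53-specific  — any hit on the TP53 readout, assigned independently of the
  categories above (a gene may be joint *and* a TP53 regulator).

Secondary-screen validation rescores a rescreened (DMSO-only) pool at a
relaxed 1-SD cut-off; primary CDKN1A/BBC3 regulators present in the pool but
not re-called become putative false positives.  A second, orthogonal filter
flags hit genes recorded as not expressed (value 0) in an external
expression table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateConditionError
from .screen_io import (
    COLUMN_LABELS,
    CONDITIONS,
    ScreenMatrix,
    condition_label,
    parse_condition,
)

DEFAULT_THRESHOLD = 2.0
DEFAULT_SECONDARY_THRESHOLD = 1.0

POSITIVE_REGULATOR = "positive_regulator"
NEGATIVE_REGULATOR = "negative_regulator"

CATEGORIES = ("joint", "CDKN1A_specific", "BBC3_specific", "TP53_specific")


@dataclass
class ZScoreTable:
    """Standard scores with the population statistics that produced them."""

    z: pd.DataFrame  # gene x 6 conditions
    mu: pd.Series  # per-condition library mean
    theta: pd.Series  # per-condition library sample SD (ddof=1)
    n_used: pd.Series  # per-condition count of values entering mu/theta
    roles: pd.Series  # gene -> role, carried from the matrix

    @property
    def genes(self) -> list[str]:
        return list(self.z.index)


@dataclass(frozen=True)
class HitCall:
    gene: str
    readout: str
    treatment: str
    z: float
    direction: str  # positive_regulator (z < -tau) | negative_regulator (z > tau)
    threshold: float

    @property
    def condition(self) -> str:
        return condition_label(self.readout, self.treatment)


@dataclass
class GeneClassification:
    """Per-gene classification record."""

    gene: str
    categories: set[str] = field(default_factory=set)
    hits: dict[tuple[str, str], HitCall] = field(default_factory=dict)
    #: treatment -> direction for joint calls
    joint_detail: dict[str, str] = field(default_factory=dict)
    secondary_status: str = "not_retested"  # confirmed | not_confirmed | not_retested
    low_expression_flag: bool = False

    @property
    def category(self) -> str:
        """Single summary label (joint takes precedence; 'none' if no hits)."""
        for cat in CATEGORIES:
            if cat in self.categories:
                return cat
        return "none"


@dataclass
class RegulatorClassification:
    """Classification of every gene with at least one hit, plus run metadata."""

    genes: dict[str, GeneClassification]
    threshold: float
    #: genes looked up in but absent from the external expression table
    missing_from_expression: list[str] = field(default_factory=list)

    def with_category(self, category: str) -> list[GeneClassification]:
        return [gc for gc in self.genes.values() if category in gc.categories]

    def hit_genes(self) -> set[str]:
        return {g for g, gc in self.genes.items() if gc.categories}

    # rows for screen_io.write_hit_tables -----------------------------------
    def category_rows(self, category: str):
        rows = []
        for gc in self.with_category(category):
            if category == "joint":
                for treatment, direction in gc.joint_detail.items():
                    pair = [
                        gc.hits.get(("CDKN1A", treatment)),
                        gc.hits.get(("BBC3", treatment)),
                    ]
                    z = max(
                        (h.z for h in pair if h is not None), key=abs, default=np.nan
                    )
                    rows.append(
                        (
                            direction,
                            treatment,
                            gc.gene,
                            z,
                            gc.secondary_status,
                            gc.low_expression_flag,
                        )
                    )
            else:
                readout = category.split("_")[0]
                for (r, treatment), hit in gc.hits.items():
                    if r != readout:
                        continue
                    if category != "TP53_specific" and not self._is_specific_cell(
                        gc, r, treatment
                    ):
                        continue
                    rows.append(
                        (
                            hit.direction,
                            treatment,
                            gc.gene,
                            hit.z,
                            gc.secondary_status,
                            gc.low_expression_flag,
                        )
                    )
        return rows

    @staticmethod
    def _is_specific_cell(gc: GeneClassification, readout: str, treatment: str) -> bool:
        partner = "BBC3" if readout == "CDKN1A" else "CDKN1A"
        return (partner, treatment) not in gc.hits


# ---------------------------------------------------------------------------
# z-scores and hits
# ---------------------------------------------------------------------------


def compute_zscores(matrix: ScreenMatrix, include_controls: bool = False) -> ZScoreTable:
    """Column-wise standard scores against the library population.

    mu and theta for each condition are computed over the non-missing values
    of the included genes (library entries only unless ``include_controls``);
    theta is the sample standard deviation (ddof=1).  Every gene — controls
    included — is then scored against those statistics.  Missing values stay
    missing.

    A column whose included values are constant raises
    :class:`DegenerateConditionError`; a column with no data at all is left
    entirely missing (this is how DMSO-only secondary screens flow through).
    """
    included = (
        matrix.values
        if include_controls
        else matrix.values.loc[matrix.roles == "library"]
    )
    mu = pd.Series(np.nan, index=list(COLUMN_LABELS))
    theta = pd.Series(np.nan, index=list(COLUMN_LABELS))
    n_used = pd.Series(0, index=list(COLUMN_LABELS), dtype=int)
    for col in COLUMN_LABELS:
        vals = included[col].dropna()
        n_used[col] = len(vals)
        if len(vals) == 0:
            continue
        if len(vals) < 2:
            raise DegenerateConditionError(
                f"condition {col}: need >= 2 non-missing values, got {len(vals)}"
            )
        sd = float(vals.std(ddof=1))
        if sd == 0:
            raise DegenerateConditionError(f"condition {col}: zero spread")
        mu[col], theta[col] = float(vals.mean()), sd
    z = (matrix.values - mu) / theta
    return ZScoreTable(z=z, mu=mu, theta=theta, n_used=n_used, roles=matrix.roles.copy())


def call_hits(ztable: ZScoreTable, threshold: float = DEFAULT_THRESHOLD) -> list[HitCall]:
    """All (gene, condition) cells with |z| strictly above ``threshold``.

    Values exactly at +/-threshold sit inside the non-hit window.  Direction
    follows the sign of z: below -threshold the knockdown lowered expression,
    so the gene is called a positive regulator of that readout.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    hits: list[HitCall] = []
    for gene in ztable.genes:
        for readout, treatment in CONDITIONS:
            z = ztable.z.at[gene, condition_label(readout, treatment)]
            if pd.isna(z) or abs(z) <= threshold:
                continue
            direction = POSITIVE_REGULATOR if z < 0 else NEGATIVE_REGULATOR
            hits.append(
                HitCall(
                    gene=gene,
                    readout=readout,
                    treatment=treatment,
                    z=float(z),
                    direction=direction,
                    threshold=threshold,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def classify_regulators(hits: list[HitCall]) -> RegulatorClassification:
    """Map per-condition hits onto regulator categories (see module docstring)."""
    threshold = hits[0].threshold if hits else DEFAULT_THRESHOLD
    genes: dict[str, GeneClassification] = {}
    for hit in hits:
        gc = genes.setdefault(hit.gene, GeneClassification(gene=hit.gene))
        gc.hits[(hit.readout, hit.treatment)] = hit

    for gc in genes.values():
        # joint: same-direction CDKN1A & BBC3 hits in the same treatment
        for treatment in ("DMSO", "etoposide"):
            a = gc.hits.get(("CDKN1A", treatment))
            b = gc.hits.get(("BBC3", treatment))
            if a is not None and b is not None and a.direction == b.direction:
                gc.categories.add("joint")
                gc.joint_detail[treatment] = a.direction
        # readout-specific (only for genes never joint, per-treatment partner rule)
        if "joint" not in gc.categories:
            for readout, partner in (("CDKN1A", "BBC3"), ("BBC3", "CDKN1A")):
                for treatment in ("DMSO", "etoposide"):
                    if (readout, treatment) in gc.hits and (
                        partner,
                        treatment,
                    ) not in gc.hits:
                        gc.categories.add(f"{readout}_specific")
        # TP53 regulators are tracked independently of the categories above
        if any(r == "TP53" for r, _ in gc.hits):
            gc.categories.add("TP53_specific")

    return RegulatorClassification(genes=genes, threshold=threshold)


# ---------------------------------------------------------------------------
# secondary-screen validation and expression-based flagging
# ---------------------------------------------------------------------------


def validate_secondary(
    classification: RegulatorClassification,
    secondary: ScreenMatrix,
    threshold: float = DEFAULT_SECONDARY_THRESHOLD,
    require_direction: bool = True,
) -> RegulatorClassification:
    """Confirm primary CDKN1A/BBC3 regulators against a rescreened pool.

    The secondary screen is scored internally over its own (DMSO-only) pool.
    A primary regulator present in the pool is ``confirmed`` when at least one
    readout it was originally a hit for shows |secondary z| > ``threshold``
    (with matching direction unless ``require_direction`` is False);
    otherwise it is ``not_confirmed`` — a putative false positive.  Genes
    absent from the pool remain ``not_retested``.  TP53-only regulators are
    not rescreened and are left untouched.
    """
    if len(secondary.genes) == 0:
        warnings.warn("empty secondary pool: all genes left not_retested")
        return classification
    ztable = compute_zscores(secondary)
    pool = {g.casefold(): g for g in secondary.genes}

    for gene, gc in classification.genes.items():
        primary = [
            hit for (r, _), hit in gc.hits.items() if r in ("CDKN1A", "BBC3")
        ]
        if not primary:
            continue  # TP53-only regulator: not part of the rescreen design
        match = pool.get(gene.casefold())
        if match is None:
            gc.secondary_status = "not_retested"
            continue
        confirmed = False
        for hit in primary:
            z2 = ztable.z.at[match, condition_label(hit.readout, "DMSO")]
            if pd.isna(z2) or abs(z2) <= threshold:
                continue
            if require_direction:
                same_sign = (z2 < 0) == (hit.direction == POSITIVE_REGULATOR)
                if not same_sign:
                    continue
            confirmed = True
            break
        gc.secondary_status = "confirmed" if confirmed else "not_confirmed"
    return classification


def flag_low_expression(
    classification: RegulatorClassification, expression
) -> RegulatorClassification:
    """Flag hit genes whose external expression value is exactly 0.

    ``expression`` maps gene symbol -> expression value (dict or Series);
    the join is case-insensitive.  Genes missing from the table are left
    unflagged and recorded in ``classification.missing_from_expression``.
    """
    if isinstance(expression, pd.Series):
        expression = expression.to_dict()
    table = {str(k).casefold(): float(v) for k, v in expression.items()}
    missing = []
    for gene, gc in classification.genes.items():
        value = table.get(gene.casefold())
        if value is None:
            missing.append(gene)
            continue
        if value == 0:
            gc.low_expression_flag = True
    classification.missing_from_expression = missing
    return classification


def hit_summary(hits: list[HitCall]) -> pd.DataFrame:
    """Tidy DataFrame view of a hit list (one row per gene x condition hit)."""
    return pd.DataFrame(
        [
            (h.gene, h.readout, h.treatment, h.z, h.direction)
            for h in hits
        ],
        columns=["gene", "readout", "treatment", "z", "direction"],
    )
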