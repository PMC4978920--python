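"""Seeded generator of synthetic siRNA screens with planted regulator effects.

The generator emulates the structure of the real experiment — a library of
~589 chromatin-regulator siRNAs plated with nontargeting, TP53 and MDM2
control wells, three p53 target readouts under DMSO and etoposide — so that
every pipeline stage can be exercised and scored against a known ground
truth:

* a configurable fraction of library genes carries a planted log2
  fold-change on the readouts its category dictates (joint CDKN1A+BBC3
  regulators, single-readout regulators, TP53 regulators), in the basal
  condition, the stimulated condition, or both;
* the library's own TP53 entry carries a strong knockdown effect on all
  three readouts in both treatments (TP53 transcribes them all, and targets
  its own locus), which downstream should be called as a hit in all six
  conditions;
* nontargeting controls carry no effect, TP53 control wells mirror the TP53
  library entry, and MDM2 control wells raise basal CDKN1A/BBC3 only (MDM2
  acts post-transcriptionally on p53 protein, so TP53 mRNA is untouched and
  etoposide-stimulated levels are already saturated);
* technical noise is multiplicative lognormal (qPCR ratio errors compound
  multiplicatively and the normalized ratios must stay non-negative), with a
  per-plate multiplicative offset on top;
* optionally, raw triplicate Ct values are emitted by inverting per-amplicon
  standard curves, so the quantification stage can be tested end to end.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError
from .screen_io import (
    COLUMN_LABELS,
    CONDITIONS,
    READOUTS,
    REFERENCE_GENE,
    TREATMENTS,
    ScreenMatrix,
    condition_label,
)
from .qpcr_quant import StandardCurve

PERFECT_SLOPE = -1.0 / math.log10(2.0)  # one doubling per cycle: -3.3219...

REGULATOR_CATEGORIES = (
    "joint_positive",
    "joint_negative",
    "CDKN1A_specific",
    "BBC3_specific",
    "TP53_specific",
)


def _default_fractions() -> dict[str, float]:
    # 2% of the library per category (~10% regulators overall), in line with
    # the ~10-15% hit-gene rate of real targeted chromatin screens.
    return {cat: 0.02 for cat in REGULATOR_CATEGORIES}


def _default_baseline() -> dict[str, float]:
    # Basal ratios near 1; etoposide elevates the p53 targets (p53 induction)
    # but barely changes TP53 mRNA itself.  Placeholder magnitudes chosen to
    # look like a typical DNA-damage induction; configurable.
    return {
        "CDKN1A:DMSO": 1.0,
        "CDKN1A:etoposide": 4.0,
        "BBC3:DMSO": 1.0,
        "BBC3:etoposide": 3.0,
        "TP53:DMSO": 1.0,
        "TP53:etoposide": 1.2,
    }


def _default_controls() -> dict[str, int]:
    return {"nontargeting_control": 2, "tp53_control": 2, "mdm2_control": 2}


def _default_intercepts() -> dict[str, float]:
    return {"CDKN1A": 26.0, "BBC3": 28.0, "TP53": 25.0, REFERENCE_GENE: 22.0}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic screen.

    ``condition_of_effect`` controls the treatment in which planted effects
    act: ``"DMSO"``, ``"etoposide"``, ``"both"``, or ``"mixed"`` (each
    regulator drawn uniformly from the three, mirroring the variety seen in
    real screens).  ``effect_log2`` is the planted |log2 fold-change|;
    ``noise_cv`` the coefficient of variation of the multiplicative lognormal
    technical noise; ``plate_effect_sd`` the SD of the per-plate log offset.
    """

    n_genes: int = 589
    fractions: dict[str, float] = field(default_factory=_default_fractions)
    effect_log2: float = 1.5
    condition_of_effect: str = "mixed"
    baseline: dict[str, float] = field(default_factory=_default_baseline)
    noise_cv: float = 0.15
    plate_effect_sd: float = 0.05
    n_plates: int = 7
    controls_per_plate: dict[str, int] = field(default_factory=_default_controls)
    tp53_knockdown_log2: float = 2.5
    mdm2_effect_log2: float = 1.0
    emit_ct: bool = False
    ct_noise_sd: float = 0.0
    n_ct_replicates: int = 3
    dilution_points: int = 5
    dilution_factor: float = 4.0
    curve_intercepts: dict[str, float] = field(default_factory=_default_intercepts)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ConfigError("n_genes must be >= 10")
        unknown = set(self.fractions) - set(REGULATOR_CATEGORIES)
        if unknown:
            raise ConfigError(f"unknown regulator categories {sorted(unknown)}")
        if any(f < 0 for f in self.fractions.values()) or sum(
            self.fractions.values()
        ) > 1:
            raise ConfigError("fractions must be non-negative and sum to <= 1")
        if self.noise_cv < 0 or self.plate_effect_sd < 0 or self.ct_noise_sd < 0:
            raise ConfigError("noise parameters must be >= 0")
        if self.condition_of_effect not in ("DMSO", "etoposide", "both", "mixed"):
            raise ConfigError(
                f"condition_of_effect {self.condition_of_effect!r} invalid"
            )
        if self.n_plates < 1:
            raise ConfigError("n_plates must be >= 1")


@dataclass
class SimulationTruth:
    """Planted ground truth: per-entry effects, categories and noise state."""

    config: SimulationConfig
    effects: pd.DataFrame  # entry x 6 conditions, log2 effect
    category: pd.Series  # entry -> planted category / control role / "none"
    roles: pd.Series  # entry -> screen role
    plates: pd.Series  # entry -> plate id
    plate_factors: pd.DataFrame  # plate x 6 multiplicative factors
    curves: dict[str, StandardCurve] | None = None

    def planted_regulators(self) -> set[str]:
        """Library genes carrying any nonzero planted effect."""
        lib = self.roles == "library"
        nonzero = (self.effects != 0).any(axis=1)
        return set(self.effects.index[lib & nonzero])


def _lognormal_sigma(cv: float) -> float:
    return math.sqrt(math.log(1.0 + cv * cv))


def _noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Multiplicative lognormal noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(shape)
    sigma = _lognormal_sigma(cv)
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=shape))


def _treatments_for(rng: np.random.Generator, mode: str) -> tuple[str, ...]:
    if mode == "both":
        return TREATMENTS
    if mode in TREATMENTS:
        return (mode,)
    # mixed: uniform over {DMSO, etoposide, both}
    pick = rng.integers(0, 3)
    return TREATMENTS if pick == 2 else (TREATMENTS[pick],)


def _plant_effects(
    config: SimulationConfig, genes: list[str], rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.Series]:
    effects = pd.DataFrame(0.0, index=genes, columns=list(COLUMN_LABELS))
    category = pd.Series("none", index=genes)

    # The library's own TP53 entry: strong knockdown of all readouts, always.
    if "TP53" in effects.index:
        effects.loc["TP53", :] = -config.tp53_knockdown_log2
        category["TP53"] = "TP53_knockdown"

    eligible = [g for g in genes if g != "TP53"]
    rng.shuffle(eligible)
    cursor = 0
    for cat in REGULATOR_CATEGORIES:
        n_cat = int(round(config.fractions.get(cat, 0.0) * config.n_genes))
        chosen, cursor = eligible[cursor : cursor + n_cat], cursor + n_cat
        for gene in chosen:
            category[gene] = cat
            treatments = _treatments_for(rng, config.condition_of_effect)
            if cat == "joint_positive":
                readouts, sign = ("CDKN1A", "BBC3"), -1.0
            elif cat == "joint_negative":
                readouts, sign = ("CDKN1A", "BBC3"), +1.0
            elif cat == "CDKN1A_specific":
                readouts, sign = ("CDKN1A",), float(rng.choice([-1.0, 1.0]))
            elif cat == "BBC3_specific":
                readouts, sign = ("BBC3",), float(rng.choice([-1.0, 1.0]))
            else:  # TP53_specific
                readouts, sign = ("TP53",), float(rng.choice([-1.0, 1.0]))
            for r in readouts:
                for t in treatments:
                    effects.at[gene, condition_label(r, t)] = sign * config.effect_log2
    return effects, category


def _control_entries(config: SimulationConfig) -> tuple[list[str], list[str], list[str]]:
    names, roles, plates = [], [], []
    for p in range(1, config.n_plates + 1):
        plate = f"P{p:02d}"
        for role, count in config.controls_per_plate.items():
            stem = {
                "nontargeting_control": "NTC",
                "tp53_control": "siTP53",
                "mdm2_control": "siMDM2",
            }[role]
            for k in range(1, count + 1):
                names.append(f"{stem}_{plate}_{k}")
                roles.append(role)
                plates.append(plate)
    return names, roles, plates


def simulate_screen(
    config: SimulationConfig | None = None,
) -> tuple[ScreenMatrix, SimulationTruth] | tuple[ScreenMatrix, pd.DataFrame, SimulationTruth]:
    """Generate one synthetic screen.

    Returns ``(matrix, truth)``, or ``(matrix, ct_records, truth)`` when
    ``config.emit_ct`` — the Ct table is built by inverting per-amplicon
    standard curves so that at zero cycle noise the quantification pipeline
    reproduces ``matrix`` exactly.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)

    genes = ["TP53"] + [f"CR{i:04d}" for i in range(1, config.n_genes)]
    effects, category = _plant_effects(config, genes, rng)

    # plate layout: library genes in contiguous blocks, controls on each plate
    per_plate = math.ceil(config.n_genes / config.n_plates)
    gene_plates = [f"P{(i // per_plate) + 1:02d}" for i in range(config.n_genes)]
    ctl_names, ctl_roles, ctl_plates = _control_entries(config)

    entries = genes + ctl_names
    roles = pd.Series(
        ["library"] * config.n_genes + ctl_roles, index=entries, name="role"
    )
    plates = pd.Series(gene_plates + ctl_plates, index=entries, name="plate")

    # control effects
    ctl_effects = pd.DataFrame(0.0, index=ctl_names, columns=list(COLUMN_LABELS))
    ctl_category = pd.Series(ctl_roles, index=ctl_names)
    for name, role in zip(ctl_names, ctl_roles):
        if role == "tp53_control":
            ctl_effects.loc[name, :] = -config.tp53_knockdown_log2
        elif role == "mdm2_control":
            ctl_effects.at[name, "CDKN1A:DMSO"] = config.mdm2_effect_log2
            ctl_effects.at[name, "BBC3:DMSO"] = config.mdm2_effect_log2
    effects = pd.concat([effects, ctl_effects])
    category = pd.concat([category, ctl_category])

    plate_ids = sorted(set(plates))
    if config.plate_effect_sd > 0:
        pf = np.exp(
            rng.normal(0.0, config.plate_effect_sd, size=(len(plate_ids), 6))
        )
    else:
        pf = np.ones((len(plate_ids), 6))
    plate_factors = pd.DataFrame(pf, index=plate_ids, columns=list(COLUMN_LABELS))

    baseline = np.array([config.baseline[c] for c in COLUMN_LABELS])
    noise = _noise(rng, config.noise_cv, (len(entries), 6))
    values = (
        baseline[None, :]
        * np.power(2.0, effects.to_numpy())
        * plate_factors.loc[plates, :].to_numpy()
        * noise
    )
    matrix = ScreenMatrix(
        pd.DataFrame(values, index=entries, columns=list(COLUMN_LABELS)), roles
    )
    truth = SimulationTruth(
        config=config,
        effects=effects,
        category=category,
        roles=roles,
        plates=plates,
        plate_factors=plate_factors,
    )
    if not config.emit_ct:
        return matrix, truth

    curves = {
        amplicon: StandardCurve(
            readout=amplicon,
            slope=PERFECT_SLOPE,
            intercept=config.curve_intercepts[amplicon],
            r_squared=1.0,
            efficiency=1.0,
        )
        for amplicon in (*READOUTS, REFERENCE_GENE)
    }
    truth.curves = curves
    ct_records = _emit_ct_records(matrix, curves, config, rng)
    return matrix, ct_records, truth


def _ct_of(q: float, curve: StandardCurve) -> float:
    return curve.intercept + curve.slope * math.log10(q)


def _emit_ct_records(
    matrix: ScreenMatrix,
    curves: dict[str, StandardCurve],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Invert the planted curves into triplicate Ct rows plus standard rows.

    The reference amplicon gets its own per-well relative amount (lognormal
    around 1), and each target amount is the normalized value times that
    reference amount — so reference normalization cancels the extra factor
    exactly when cycle noise is zero.
    """
    rows = []
    for readout, curve in curves.items():
        for i in range(config.dilution_points):
            q = config.dilution_factor ** (-i)
            rows.append(
                ("STD", readout, "DMSO", 1, _ct_of(q, curve), "standard", q)
            )
    for gene in matrix.genes:
        role = matrix.roles[gene]
        for treatment in TREATMENTS:
            ref_q = float(_noise(rng, 0.10, ())) if config.noise_cv > 0 else 1.0
            amounts = {REFERENCE_GENE: ref_q}
            for readout in READOUTS:
                v = matrix.values.at[gene, condition_label(readout, treatment)]
                amounts[readout] = float(v) * ref_q
            for readout, q in amounts.items():
                base_ct = _ct_of(q, curves[readout])
                for rep in range(1, config.n_ct_replicates + 1):
                    ct = base_ct + (
                        rng.normal(0.0, config.ct_noise_sd)
                        if config.ct_noise_sd > 0
                        else 0.0
                    )
                    rows.append((gene, readout, treatment, rep, ct, role, math.nan))
    return pd.DataFrame(
        rows,
        columns=["gene", "readout", "treatment", "replicate", "ct", "role", "quantity"],
    )


def simulate_secondary(
    truth: SimulationTruth,
    subset_size: int = 81,
    seed: int = 0,
    drop_effects: tuple[str, ...] = (),
    genes: list[str] | None = None,
) -> ScreenMatrix:
    """Rescreen a random library subset under DMSO only, with fresh noise.

    ``drop_effects`` lists genes whose planted effect is removed in the
    rescreen — synthetic false positives that the validation stage should
    fail to confirm.  Only the CDKN1A and BBC3 DMSO columns are measured;
    the other four stay missing.  Pass ``genes`` to fix the pool explicitly.
    """
    rng = np.random.default_rng(seed)
    library = list(truth.roles.index[truth.roles == "library"])
    if genes is None:
        if subset_size > len(library):
            raise ConfigError("subset_size exceeds library size")
        idx = rng.choice(len(library), size=subset_size, replace=False)
        genes = [library[i] for i in sorted(idx)]
    config = truth.config
    cols = ["CDKN1A:DMSO", "BBC3:DMSO"]
    eff = truth.effects.loc[genes, cols].copy()
    eff.loc[eff.index.isin(drop_effects), :] = 0.0
    base = np.array([config.baseline[c] for c in cols])
    noise = _noise(rng, config.noise_cv, (len(genes), len(cols)))
    vals = base[None, :] * np.power(2.0, eff.to_numpy()) * noise
    values = pd.DataFrame(np.nan, index=genes, columns=list(COLUMN_LABELS))
    values[cols] = vals
    return ScreenMatrix(values, truth.roles.loc[genes].copy())


def score_recovery(truth: SimulationTruth, classification) -> dict:
    """Precision/recall of called hit genes against the planted regulators.

    Restricted to library entries (dedicated control wells are not scored).
    Returns overall precision and recall (NaN when undefined), per-category
    recall, and a planted-category x called-category confusion table.
    """
    library = set(truth.roles.index[truth.roles == "library"])
    planted = truth.planted_regulators()
    called = classification.hit_genes() & library
    tp = len(called & planted)
    precision = tp / len(called) if called else math.nan
    recall = tp / len(planted) if planted else math.nan

    per_category_recall: dict[str, float] = {}
    for cat in (*REGULATOR_CATEGORIES, "TP53_knockdown"):
        members = {
            g
            for g in library
            if truth.category.get(g) == cat and g in planted
        }
        if members:
            per_category_recall[cat] = len(members & called) / len(members)

    called_cat = {
        g: classification.genes[g].category if g in classification.genes else "none"
        for g in library
    }
    confusion = (
        pd.DataFrame(
            {
                "planted": [truth.category.get(g, "none") for g in sorted(library)],
                "called": [called_cat[g] for g in sorted(library)],
            }
        )
        .groupby(["planted", "called"])
        .size()
        .unstack(fill_value=0)
    )
    return {
        "precision": precision,
        "recall": recall,
        "n_planted": len(planted),
        "n_called": len(called),
        "per_category_recall": per_category_recall,
        "confusion": confusion,
    }
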