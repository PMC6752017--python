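"""Net product formation and carbon / reducing-equivalent recovery tables.

Microcosm product time courses (umol per g fresh weight) are reduced to net
amounts formed over the incubation, corrected for the unsupplemented control:

    net = (treatment[t_end] - treatment[0]) - (control[t_end] - control[0])

on replicate means.  Products with no net increase relative to the control
are flagged and carry 0 (rendered as an em dash in reports).  Recoveries then
express, per product, the percentage of the substrate dose's carbon and of
its reducing equivalents (electrons by the degree-of-reduction rule) found in
that product; CO2 carries no reducing equivalents and H2 no carbon, so those
cells are "not applicable".  The dose denominator is either the amount of
substrate provided or the amount consumed (measured disappearance of the
substrate), matching the two bases used for amino acid versus saccharide /
intermediate treatments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .chem_core import Compound, electrons_per_molecule

__all__ = [
    "MeasurementSeries",
    "SubstrateDose",
    "RecoveryTable",
    "CollectiveProducts",
    "measurements_to_frame",
    "net_product_formation",
    "per_replicate_deltas",
    "per_replicate_net",
    "carbon_recovery",
    "electron_recovery",
    "recovery_table",
    "collective_products",
    "welch_t_test",
    "ammonium_calibration",
]

MEASUREMENT_COLUMNS = (
    "treatment",
    "replicate",
    "time_h",
    "analyte",
    "amount_umol_per_gfw",
)


@dataclass
class MeasurementSeries:
    """One (treatment, replicate, analyte) time course in umol/gFW."""

    treatment: str
    replicate: str | int
    analyte: str
    times_h: tuple[float, ...]
    amounts: tuple[float, ...]

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times_h)
        amounts = tuple(float(a) for a in self.amounts)
        if len(times) != len(amounts) or not times:
            raise ValueError("times and amounts must be equal-length and non-empty")
        if times[0] != 0.0:
            raise ValueError("the first time point must be 0 h")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("time points must be strictly increasing")
        if any(a < 0 for a in amounts):
            raise ValueError("amounts must be non-negative")
        self.times_h, self.amounts = times, amounts


def measurements_to_frame(series: list[MeasurementSeries]) -> pd.DataFrame:
    """Stack measurement series into the long-format table the pipeline reads."""
    rows = [
        (s.treatment, s.replicate, t, s.analyte, a)
        for s in series
        for t, a in zip(s.times_h, s.amounts)
    ]
    return pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS))


def _mean_deltas(df: pd.DataFrame, treatment: str, t_end: float) -> pd.Series:
    """Replicate-mean (t_end - t0) change per analyte for one treatment."""
    sub = df[df["treatment"] == treatment]
    if sub.empty:
        raise ValueError(f"no measurements for treatment {treatment!r}")
    wide = sub.pivot_table(
        index="analyte", columns="time_h", values="amount_umol_per_gfw", aggfunc="mean"
    )
    for t in (0.0, float(t_end)):
        if t not in wide.columns:
            raise ValueError(f"treatment {treatment!r} has no time point {t} h")
    return wide[float(t_end)] - wide[0.0]


def net_product_formation(
    df: pd.DataFrame,
    treatment: str,
    control: str,
    t_end: float = 30.0,
    exclude: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Control-corrected net product formation on replicate means.

    Returns a frame indexed by analyte with columns ``net`` (clamped at 0),
    ``net_raw`` (signed, for audit) and ``formed`` (bool).  Analytes absent
    from the control are treated as control delta 0 with a warning; analytes
    in ``exclude`` (typically the supplemented substrate) are dropped.
    """
    d_trt = _mean_deltas(df, treatment, t_end)
    d_ctl = _mean_deltas(df, control, t_end)
    missing = d_trt.index.difference(d_ctl.index)
    if len(missing):
        warnings.warn(
            f"analytes missing from control {control!r} treated as 0: "
            f"{sorted(missing)}",
            stacklevel=2,
        )
    net_raw = d_trt - d_ctl.reindex(d_trt.index, fill_value=0.0)
    net_raw = net_raw.drop(index=[a for a in exclude if a in net_raw.index])
    out = pd.DataFrame(
        {
            "net": net_raw.clip(lower=0.0).where(net_raw > 0, 0.0),
            "net_raw": net_raw,
            "formed": net_raw > 0,
        }
    )
    out.index.name = "analyte"
    return out


def per_replicate_deltas(
    df: pd.DataFrame, treatment: str, t_end: float = 30.0
) -> pd.DataFrame:
    """(t_end - t0) change per replicate (rows) and analyte (columns)."""
    sub = df[df["treatment"] == treatment]
    if sub.empty:
        raise ValueError(f"no measurements for treatment {treatment!r}")
    wide = sub.pivot_table(
        index=["replicate", "analyte"], columns="time_h",
        values="amount_umol_per_gfw",
    )
    for t in (0.0, float(t_end)):
        if t not in wide.columns:
            raise ValueError(f"treatment {treatment!r} has no time point {t} h")
    delta = (wide[float(t_end)] - wide[0.0]).unstack("analyte")
    return delta


def per_replicate_net(
    df: pd.DataFrame,
    treatment: str,
    control: str,
    t_end: float = 30.0,
    exclude: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Per-replicate treatment deltas minus the control's replicate-mean delta."""
    d_trt = per_replicate_deltas(df, treatment, t_end)
    d_ctl = _mean_deltas(df, control, t_end)
    net = d_trt.sub(d_ctl.reindex(d_trt.columns, fill_value=0.0), axis=1)
    return net.drop(columns=[a for a in exclude if a in net.columns])


@dataclass
class SubstrateDose:
    """Substrate amount the recovery denominator refers to.

    ``basis="provided"`` uses the supplemented amount; ``basis="consumed"``
    uses the measured disappearance (initial minus final replicate-mean
    substrate), clamped into [0, provided] so measurement noise cannot
    produce a negative or super-dose denominator.
    """

    compound: Compound
    provided: float
    basis: str = "provided"
    consumed: float | None = None

    def __post_init__(self) -> None:
        if self.provided <= 0:
            raise ValueError("provided amount must be positive")
        if self.basis not in ("provided", "consumed"):
            raise ValueError(f"unknown basis {self.basis!r}")
        if self.basis == "consumed" and self.consumed is None:
            raise ValueError("basis='consumed' requires a consumed amount; "
                             "use consumed_from_measurements")

    @classmethod
    def consumed_from_measurements(
        cls,
        compound: Compound,
        provided: float,
        df: pd.DataFrame,
        treatment: str,
        analyte: str,
        t_end: float = 30.0,
    ) -> "SubstrateDose":
        delta = _mean_deltas(df, treatment, t_end)
        if analyte not in delta.index:
            raise ValueError(f"substrate analyte {analyte!r} not measured in "
                             f"treatment {treatment!r}")
        consumed = -float(delta[analyte])
        if consumed < 0:
            warnings.warn("negative consumed-substrate estimate clamped to 0",
                          stacklevel=2)
            consumed = 0.0
        consumed = min(consumed, provided)
        return cls(compound, provided, basis="consumed", consumed=consumed)

    @property
    def amount(self) -> float:
        return self.provided if self.basis == "provided" else float(self.consumed)


@dataclass
class RecoveryTable:
    """Per-product % carbon and reducing-equivalent recoveries plus totals.

    NaN cells are "not applicable" (CO2 has no reducing equivalents, H2 no
    carbon); products with ``formed == False`` render as an em dash.
    """

    table: pd.DataFrame  # index product; columns carbon, re, formed
    total_carbon: float
    total_re: float


def _registry_lookup(registry: dict[str, Compound], name: str) -> Compound:
    try:
        return registry[name.lower()]
    except KeyError:
        raise KeyError(f"product {name!r} missing from the compound registry") from None


def recovery_table(
    net: pd.DataFrame,
    dose: SubstrateDose,
    registry: dict[str, Compound],
) -> RecoveryTable:
    """Carbon and reducing-equivalent recovery percentages for a net-product table."""
    if dose.amount <= 0:
        raise ValueError("dose amount (denominator) must be positive")
    sub = dose.compound
    denom_c = dose.amount * sub.carbons
    denom_e = dose.amount * electrons_per_molecule(sub)
    carbon, re_, formed = {}, {}, {}
    for analyte, row in net.iterrows():
        comp = _registry_lookup(registry, analyte)
        c_p = comp.carbons
        e_p = electrons_per_molecule(comp)
        carbon[analyte] = (
            np.nan if c_p == 0 else 100.0 * row["net"] * c_p / denom_c
        )
        re_[analyte] = np.nan if e_p == 0 else 100.0 * row["net"] * e_p / denom_e
        formed[analyte] = bool(row["formed"])
    table = pd.DataFrame({"carbon": carbon, "re": re_, "formed": formed})
    table.index.name = "product"
    return RecoveryTable(
        table=table,
        total_carbon=float(np.nansum(list(carbon.values()))) if carbon else 0.0,
        total_re=float(np.nansum(list(re_.values()))) if re_ else 0.0,
    )


def carbon_recovery(
    net: pd.DataFrame, dose: SubstrateDose, registry: dict[str, Compound]
) -> pd.Series:
    """Per-product % of the substrate dose's carbon (NaN where not applicable)."""
    return recovery_table(net, dose, registry).table["carbon"]


def electron_recovery(
    net: pd.DataFrame, dose: SubstrateDose, registry: dict[str, Compound]
) -> pd.Series:
    """Per-product % of the substrate dose's reducing equivalents."""
    return recovery_table(net, dose, registry).table["re"]


@dataclass
class CollectiveProducts:
    """Per-replicate collective product sums (umol/gFW) with mean and SD."""

    sums: pd.Series
    mean: float
    sd: float


def collective_products(per_replicate: pd.DataFrame) -> CollectiveProducts:
    """Sum a per-replicate net/delta table over analytes, per replicate."""
    if per_replicate.shape[0] < 1:
        raise ValueError("need at least one replicate")
    sums = per_replicate.sum(axis=1)
    sd = float(sums.std(ddof=1)) if len(sums) > 1 else 0.0
    return CollectiveProducts(sums=sums, mean=float(sums.mean()), sd=sd)


def welch_t_test(group_a, group_b) -> tuple[float, float, float]:
    """Two-sided unequal-variance (Welch) t-test.

    Returns ``(t, df, p)`` with the Welch-Satterthwaite degrees of freedom.
    Degenerate case of two zero-variance groups: identical means give p = 1,
    differing means give p = 0 with a warning.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(na + nb - 2), 1.0
        warnings.warn("both groups have zero variance; p degenerates to 0",
                      stacklevel=2)
        t = np.inf if a.mean() > b.mean() else -np.inf
        return float(t), float(na + nb - 2), 0.0
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def ammonium_calibration(
    standards,
    samples,
) -> tuple[np.ndarray, np.ndarray]:
    """Invert sample absorbances (630 nm) through a linear standard curve.

    ``standards`` is a sequence of (concentration, absorbance) pairs with
    strictly increasing concentrations.  Returns ``(concentrations,
    out_of_range)`` where the flag marks samples whose absorbance falls
    outside the standard range (extrapolated values).
    """
    std = np.asarray(standards, dtype=float)
    if std.ndim != 2 or std.shape[0] < 2:
        raise ValueError("need at least two (concentration, absorbance) standards")
    conc, absb = std[:, 0], std[:, 1]
    if np.any(np.diff(conc) <= 0):
        raise ValueError("standard concentrations must be strictly increasing")
    if np.allclose(absb, absb[0]):
        raise ValueError("singular calibration: all standard absorbances identical")
    fit = stats.linregress(conc, absb)
    y = np.asarray(samples, dtype=float)
    x = (y - fit.intercept) / fit.slope
    out_of_range = (y < absb.min()) | (y > absb.max())
    return x, out_of_range
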