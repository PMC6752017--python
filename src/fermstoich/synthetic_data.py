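"""Synthetic microcosm and community data with known ground truth.

Every analysis stage in this package can be exercised without any sequencing
download: microcosm time courses are generated from an explicit, carbon- and
electron-balanced fermentation stoichiometry; community tables plant known
responder taxa on a Dirichlet background; and representative sequences are
mutated from a common ancestor to hit requested pairwise identities.  All
generators are deterministic given their scenario and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem_core import Compound, default_registry, electrons_per_molecule
from .community_response import AbundanceTable, SampleMeta

__all__ = [
    "StoichiometricScenario",
    "CommunityScenario",
    "simulate_microcosm",
    "simulate_community",
    "simulate_sequences",
    "glutamate_scenario",
]

DNA_ALPHABET = np.array(list("ACGT"))


@dataclass
class StoichiometricScenario:
    """A microcosm treatment whose products rewrite the consumed substrate.

    ``yields`` gives mol product per mol substrate consumed and must conserve
    both carbon and electrons (within ``balance_tol`` relative); imbalanced
    stoichiometries are rejected at construction, which is the guard that
    makes noiseless recovery totals exactly 100% by construction.
    Noise is multiplicative log-normal on each observed amount (mean
    preserving, like chromatographic peak-area scatter); additive Gaussian is
    available via ``noise_model="gaussian"``.
    """

    substrate: str = "glutamate"
    dose: float = 100.0  # umol/gFW, i.e. 10 mM in the default slurry
    yields: Mapping[str, float] = field(
        default_factory=lambda: {"acetate": 1.0, "butyrate": 0.5, "co2": 1.0}
    )
    fraction_consumed: float = 1.0
    noise_sd: float = 0.0
    noise_model: str = "lognormal"
    n_replicates: int = 3
    times: Sequence[float] = (0.0, 6.0, 12.0, 18.0, 24.0, 30.0)
    background_level: float = 0.1  # control product level, fraction of planted net
    logistic_rate: float = 0.3  # 1/h
    balance_tol: float = 1e-9
    registry: Mapping[str, Compound] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.registry is None:
            self.registry = default_registry()
        if not 0.0 <= self.fraction_consumed <= 1.0:
            raise ValueError("fraction_consumed must be in [0, 1]")
        if self.dose <= 0:
            raise ValueError("dose must be positive")
        if self.noise_model not in ("lognormal", "gaussian"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        times = tuple(float(t) for t in self.times)
        if times[0] != 0.0 or any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("times must start at 0 and strictly increase")
        self.times = times
        sub = self.registry[self.substrate.lower()]
        c_in = sub.carbons
        e_in = electrons_per_molecule(sub)
        c_out = e_out = 0.0
        for product, y in self.yields.items():
            comp = self.registry[product.lower()]
            c_out += y * comp.carbons
            e_out += y * electrons_per_molecule(comp)
        tol = max(self.balance_tol, 1e-12)
        if abs(c_out - c_in) > tol * max(c_in, 1.0) or abs(e_out - e_in) > tol * max(
            e_in, 1.0
        ):
            raise ValueError(
                f"yields are not stoichiometrically balanced: carbon {c_out} vs "
                f"{c_in}, electrons {e_out} vs {e_in}; raise balance_tol only "
                "for deliberately leaky scenarios"
            )


def glutamate_scenario(**overrides) -> StoichiometricScenario:
    """Default balanced glutamate fermentation (acetate + butyrate + CO2).

    Per mol glutamate (C5, 18 e-): 1 acetate (C2, 8 e-) + 0.5 butyrate
    (C4, 20 e- -> 10) + 1 CO2 (C1, 0 e-), i.e. carbon 2+2+1=5 and electrons
    8+10+0=18, exactly balanced.
    """
    return StoichiometricScenario(**overrides)


def _progress(times: np.ndarray, t_end: float, rate: float) -> np.ndarray:
    """Logistic accumulation rescaled to 0 at t=0 and 1 at t_end."""
    f = 1.0 / (1.0 + np.exp(-rate * (times - t_end / 2.0)))
    f0, f1 = f[0], f[-1]
    return (f - f0) / (f1 - f0)


def simulate_microcosm(scenario: StoichiometricScenario) -> pd.DataFrame:
    """Long-format measurement table for a treatment and its matched control.

    The control shares the (noise-free) background product drift of the
    treatment vessels, so control subtraction recovers the planted yields
    exactly at zero noise.
    """
    rng = np.random.default_rng(scenario.seed)
    times = np.asarray(scenario.times)
    g = _progress(times, times[-1], scenario.logistic_rate)
    consumed = scenario.dose * scenario.fraction_consumed * g
    rows = []

    def observe(amount: float) -> float:
        if scenario.noise_sd == 0.0:
            return amount
        if scenario.noise_model == "lognormal":
            sd = scenario.noise_sd
            return amount * math.exp(sd * rng.standard_normal() - sd**2 / 2.0)
        return max(0.0, amount + scenario.noise_sd * rng.standard_normal())

    treatment = scenario.substrate
    for rep in range(1, scenario.n_replicates + 1):
        for trt in (treatment, "control"):
            for product, y in scenario.yields.items():
                net = y * consumed
                background = scenario.background_level * y * scenario.dose * g
                amounts = background + (net if trt == treatment else 0.0)
                for t, a in zip(times, amounts):
                    rows.append((trt, rep, t, product, observe(a)))
            substrate_amounts = (
                scenario.dose - consumed if trt == treatment else np.zeros_like(times)
            )
            for t, a in zip(times, substrate_amounts):
                rows.append((trt, rep, t, scenario.substrate, observe(a)))
    return pd.DataFrame(
        rows,
        columns=["treatment", "replicate", "time_h", "analyte", "amount_umol_per_gfw"],
    )


@dataclass
class CommunityScenario:
    """Planted-responder community layout mirroring the sequencing design.

    Background compositions are a symmetric Dirichlet draw (long-tailed,
    soil-like); at the end of incubation in a supplemented treatment each
    responder is spiked to baseline + boost (percentage points) with the
    non-responders renormalized into the remaining mass, so the planted net
    increase is exact at zero noise.
    The pooling layout matches the study design: control strata and the
    end-point RNA stratum of supplemented treatments are sequenced as three
    replicates, the remaining supplemented strata as single pooled libraries.
    Noise perturbs each taxon's fraction by a truncated Gaussian (SD in
    percentage points) followed by renormalization.
    """

    n_taxa: int = 40
    concentration: float = 0.5
    treatments: Sequence[str] = ("glutamate",)
    responders: Mapping[str, Mapping[str, float]] | None = None  # taxon->{trt: pp}
    noise_sd_points: float = 0.25
    n_replicates: int = 3
    molecules: Sequence[str] = ("DNA", "RNA")
    n_families: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.responders is None:
            boosts = (6.0, 10.0)
            self.responders = {
                f"pt{i + 1:03d}": {t: boosts[i % len(boosts)] for t in self.treatments}
                for i in range(2)
            }
        taxa = {f"pt{i + 1:03d}" for i in range(self.n_taxa)}
        unknown = set(self.responders) - taxa
        if unknown:
            raise ValueError(f"responders outside the taxon set: {sorted(unknown)}")
        for taxon, per_trt in self.responders.items():
            total = sum(per_trt.values())
            if any(b < 0 for b in per_trt.values()) or total > 100.0:
                raise ValueError(f"infeasible boost for {taxon}: {per_trt}")


def _community_layout(c: CommunityScenario) -> dict[str, SampleMeta]:
    samples: dict[str, SampleMeta] = {}
    for mol in c.molecules:
        for time in ("t0", "t_end"):
            for rep in range(1, c.n_replicates + 1):
                samples[f"control_{mol}_{time}_r{rep}"] = SampleMeta(
                    "control", time, mol, rep
                )
    for trt in c.treatments:
        for mol in c.molecules:
            # pooled single libraries except the end-point RNA stratum
            if mol == "RNA":
                samples[f"{trt}_{mol}_t0_pooled"] = SampleMeta(trt, "t0", mol, None)
                for rep in range(1, c.n_replicates + 1):
                    samples[f"{trt}_{mol}_t_end_r{rep}"] = SampleMeta(
                        trt, "t_end", mol, rep
                    )
            else:
                samples[f"{trt}_{mol}_t0_pooled"] = SampleMeta(trt, "t0", mol, None)
                samples[f"{trt}_{mol}_t_end_pooled"] = SampleMeta(trt, "t_end", mol, None)
    return samples


def simulate_community(
    c: CommunityScenario,
) -> tuple[AbundanceTable, list[str]]:
    """Abundance table plus the ground-truth responder list."""
    rng = np.random.default_rng(c.seed)
    taxa = [f"pt{i + 1:03d}" for i in range(c.n_taxa)]
    background = rng.dirichlet(np.full(c.n_taxa, c.concentration))
    layout = _community_layout(c)
    sigma = c.noise_sd_points / 100.0

    def observe(base: np.ndarray) -> np.ndarray:
        if sigma == 0.0:
            return base
        noisy = np.clip(base + sigma * rng.standard_normal(c.n_taxa), 0.0, None)
        return noisy / noisy.sum()

    data = {}
    for sample_id, meta in layout.items():
        base = background.copy()
        if meta.time == "t_end" and meta.treatment != "control":
            boost = np.zeros(c.n_taxa)
            for i, taxon in enumerate(taxa):
                boost[i] = c.responders.get(taxon, {}).get(meta.treatment, 0.0) / 100.0
            # spike-in: responders sit at baseline + boost, the background
            # renormalizes into the remaining mass, so the planted net
            # increase is exact at zero noise
            is_resp = boost > 0
            spiked = base[is_resp] + boost[is_resp]
            remaining = 1.0 - spiked.sum()
            if remaining <= 0:
                raise ValueError(
                    f"infeasible boost: spiked responders sum to {spiked.sum():.3f}"
                )
            base[~is_resp] *= remaining / base[~is_resp].sum()
            base[is_resp] = spiked
        data[sample_id] = observe(base)
    frame = pd.DataFrame(data, index=taxa)
    families = [f"Family_{(i % c.n_families) + 1:02d}" for i in range(c.n_taxa)]
    phyla = [f"Phylum_{(i % c.n_families) % 3 + 1}" for i in range(c.n_taxa)]
    lineage = {t: f"{p};{f}" for t, p, f in zip(taxa, phyla, families)}
    table = AbundanceTable(frame, layout, lineage=lineage)
    return table, sorted(c.responders)


def simulate_sequences(
    n: int,
    length: int = 250,
    divergence_plan: Sequence[float] | None = None,
    seed: int = 0,
    prefix: str = "pt",
) -> dict[str, str]:
    """Ancestor-derived sequences hitting requested identities.

    ``divergence_plan`` lists, per record, the target identity to the first
    record (the ancestor; its own entry is 1.0).  Mutated positions are
    nested across records and characters at shared positions are chosen
    pairwise distinct, so the realized identity between records i and j is
    ``min(plan[i], plan[j])`` to within the 1/length rounding of the
    substitution count.  A plan needing more than three distinct mutants at
    one position cannot be realized over a 4-letter alphabet and is rejected
    as unsatisfiable.
    """
    if n < 1 or length < 1:
        raise ValueError("need n >= 1 sequences of length >= 1")
    if divergence_plan is None:
        divergence_plan = [1.0] * n
    plan = [float(d) for d in divergence_plan]
    if len(plan) != n:
        raise ValueError("divergence_plan must have one identity per sequence")
    if any(not 0.0 <= d <= 1.0 for d in plan):
        raise ValueError("identities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    ancestor = rng.choice(DNA_ALPHABET, size=length)
    k = [round((1.0 - d) * length) for d in plan]
    positions = rng.permutation(length)
    depth = np.zeros(length, dtype=int)
    for ki in k:
        depth[positions[:ki]] += 1
    if (depth > 3).any():
        raise ValueError(
            "unsatisfiable identity plan: more than three sequences would need "
            "pairwise-distinct substitutions at one position"
        )
    names = [f"{prefix}{i + 1:03d}" for i in range(n)]
    records: dict[str, str] = {}
    used: dict[int, set[str]] = {}
    for name, ki in zip(names, k):
        seq = ancestor.copy()
        for pos in positions[:ki]:
            pos = int(pos)
            taken = used.setdefault(pos, {str(ancestor[pos])})
            choices = [b for b in DNA_ALPHABET if b not in taken]
            base = str(rng.choice(choices))
            taken.add(base)
            seq[pos] = base
        records[name] = "".join(seq)
    return records
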