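"""Synthetic data with known ground truth.

Two generators:

* :func:`simulate_orthogroups` builds small orthogroup alignments
  (default four taxa: two species from each of two locations) with
  *planted* convergent columns — every foreground taxon carries residue
  ``a``, every background taxon residue ``b != a`` — on top of a shared
  ancestral residue per column, independent per-taxon background
  substitution, and i.i.d. gaps (never inside planted columns, so the
  truth stays unambiguous).

* :func:`simulate_kinetics` draws replicate enzyme reaction rates from
  the Arrhenius law k = A·exp(−Ea/RT) with multiplicative lognormal
  noise (rates must stay positive), optionally with linear 5-minute
  assay time series per replicate.

Both are deterministic given their seed.  Neither attempts
phylogenetically realistic evolution: there is no tree, no rate
heterogeneity, no codon structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter

import numpy as np
import pandas as pd

from thermadapt.io import AMINO_ACIDS, AlignedOrthogroup, TaxonLabel

GAS_CONSTANT = 8.314  # J mol^-1 K^-1
KELVIN_OFFSET = 273.15

#: default taxa: two species, each sampled in the Arctic (foreground)
#: and Subarctic (background) location
DEFAULT_TAXA = (
    TaxonLabel("Sdroe_arctic", "S. droebachiensis", "arctic", "foreground"),
    TaxonLabel("Spall_arctic", "S. pallidus", "arctic", "foreground"),
    TaxonLabel("Sdroe_subarctic", "S. droebachiensis", "subarctic", "background"),
    TaxonLabel("Spall_subarctic", "S. pallidus", "subarctic", "background"),
)

DEFAULT_TEMPERATURES_C = (2.0, 5.0, 10.0, 15.0, 20.0, 30.0, 40.0, 50.0)


@dataclass
class OrthogroupSimSpec:
    n_orthogroups: int = 20
    alignment_length: int = 100
    taxa: tuple[TaxonLabel, ...] = DEFAULT_TAXA
    n_planted_caas: int = 10
    background_rate: float = 0.0  # per-taxon substitution prob per column
    gap_rate: float = 0.0  # per-cell gap prob outside planted columns
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_orthogroups < 1 or self.alignment_length < 1:
            raise ValueError("n_orthogroups and alignment_length must be positive")
        if self.n_planted_caas < 0:
            raise ValueError("n_planted_caas must be non-negative")
        if self.n_planted_caas > self.n_orthogroups * self.alignment_length:
            raise ValueError(
                "n_planted_caas exceeds total column capacity "
                f"({self.n_orthogroups * self.alignment_length})"
            )
        for rate in (self.background_rate, self.gap_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        roles = {t.role for t in self.taxa}
        if "foreground" not in roles or "background" not in roles:
            raise ValueError("taxa must include foreground and background roles")


@dataclass
class PlantedTruth:
    """Ground truth emitted alongside simulated orthogroups.

    ``positions`` holds (orthogroup_id, 1-based column); gains/losses
    count, per amino acid, how often it was planted as the foreground
    (gained) or background (lost) residue.
    """

    positions: set[tuple[str, int]] = field(default_factory=set)
    gains: Counter = field(default_factory=Counter)
    losses: Counter = field(default_factory=Counter)
    pairs: Counter = field(default_factory=Counter)  # (bg, fg) -> count

    def flux(self, aa: str) -> float:
        c, r = self.gains[aa], self.losses[aa]
        if c + r == 0:
            return float("nan")
        return (c - r) / (c + r)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"orthogroup_id": og, "column": col}
            for og, col in sorted(self.positions)
        ]
        return pd.DataFrame(rows, columns=["orthogroup_id", "column"])


def simulate_orthogroups(
    spec: OrthogroupSimSpec,
) -> tuple[list[AlignedOrthogroup], PlantedTruth]:
    """Generate aligned orthogroups with planted convergent columns."""
    rng = np.random.default_rng(spec.seed)
    aa = np.array(list(AMINO_ACIDS))
    n_og, length = spec.n_orthogroups, spec.alignment_length
    fg = [t.taxon_id for t in spec.taxa if t.role == "foreground"]
    bg = [t.taxon_id for t in spec.taxa if t.role == "background"]
    other = [t.taxon_id for t in spec.taxa if t.role == "excluded"]
    taxa = [t.taxon_id for t in spec.taxa]

    # planted cells chosen uniformly without replacement over all columns
    flat = rng.choice(n_og * length, size=spec.n_planted_caas, replace=False)
    planted_by_og: dict[int, set[int]] = {}
    for cell in flat:
        planted_by_og.setdefault(cell // length, set()).add(cell % length)

    truth = PlantedTruth()
    width = max(4, len(str(n_og)))
    orthogroups: list[AlignedOrthogroup] = []
    for og_idx in range(n_og):
        og_id = f"OG{og_idx:0{width}d}"
        planted = planted_by_og.get(og_idx, set())
        cols: dict[str, list[str]] = {t: [] for t in taxa}
        for col in range(length):
            ancestral = rng.choice(aa)
            if col in planted:
                # ordered distinct pair (fg residue, bg residue)
                a_idx, b_idx = rng.choice(20, size=2, replace=False)
                res_fg, res_bg = aa[a_idx], aa[b_idx]
                for t in fg:
                    cols[t].append(res_fg)
                for t in bg:
                    cols[t].append(res_bg)
                for t in other:
                    cols[t].append(ancestral)
                truth.positions.add((og_id, col + 1))
                truth.gains[str(res_fg)] += 1
                truth.losses[str(res_bg)] += 1
                truth.pairs[(str(res_bg), str(res_fg))] += 1
            else:
                for t in taxa:
                    res = ancestral
                    if spec.background_rate and rng.random() < spec.background_rate:
                        res = rng.choice(aa[aa != ancestral])
                    if spec.gap_rate and rng.random() < spec.gap_rate:
                        res = "-"
                    cols[t].append(str(res))
        orthogroups.append(
            AlignedOrthogroup(og_id, {t: "".join(cols[t]) for t in taxa})
        )
    return orthogroups, truth


@dataclass
class KineticsSimSpec:
    """Enzyme-assay simulation: replicate rates at fixed assay temperatures.

    ``populations`` maps a name to true Arrhenius parameters
    (Ea in kJ·mol⁻¹, pre-exponential factor A in rate units).
    ``sigma`` is the SD of the multiplicative lognormal rate noise.
    """

    populations: tuple[tuple[str, float, float], ...] = (
        ("arctic", 50.0, 2.0e9),
        ("subarctic", 55.0, 2.0e10),
    )
    temperatures_c: tuple[float, ...] = DEFAULT_TEMPERATURES_C
    n_replicates: int = 5
    sigma: float = 0.05
    enzyme: str = "Ala-AP"
    tissue: str = "stomach"
    n_timepoints: int = 11  # over the 5-minute assay window
    timeseries_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, ea, a in self.populations:
            if ea <= 0 or a <= 0:
                raise ValueError(f"population {name!r}: Ea and A must be positive")
        temps = list(self.temperatures_c)
        if temps != sorted(temps) or len(set(temps)) != len(temps):
            raise ValueError("temperatures must be strictly increasing")
        if self.n_replicates < 2:
            raise ValueError("need n_replicates >= 2 for any comparison")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.n_timepoints < 3:
            raise ValueError("need >= 3 time points for a slope")


def arrhenius_rate(ea_kj_mol: float, pre_exponential: float,
                   temperature_c: float) -> float:
    """Noise-free Arrhenius rate k = A·exp(−Ea/RT) at a Celsius temperature."""
    t_k = temperature_c + KELVIN_OFFSET
    return pre_exponential * np.exp(-ea_kj_mol * 1000.0 / (GAS_CONSTANT * t_k))


def simulate_kinetics(
    spec: KineticsSimSpec,
    with_timeseries: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame | None, pd.DataFrame]:
    """Draw replicate rates (and optional time series) from the Arrhenius law.

    Returns ``(rates, timeseries, truth)``.  ``rates`` has columns
    population, enzyme, tissue, temperature_C, replicate, rate.  The
    replicate index is consistent across temperatures within a
    population, standing in for one individual assayed at every
    temperature.  ``truth`` records the generating parameters.
    """
    rng = np.random.default_rng(spec.seed)
    rate_rows = []
    ts_rows = []
    for name, ea, a_factor in spec.populations:
        for temp in spec.temperatures_c:
            k_true = arrhenius_rate(ea, a_factor, temp)
            for rep in range(1, spec.n_replicates + 1):
                noise = np.exp(rng.normal(0.0, spec.sigma)) if spec.sigma else 1.0
                k = k_true * noise
                rate_rows.append(
                    {
                        "population": name,
                        "enzyme": spec.enzyme,
                        "tissue": spec.tissue,
                        "temperature_C": temp,
                        "replicate": rep,
                        "rate": k,
                    }
                )
                if with_timeseries:
                    times = np.linspace(0.0, 5.0, spec.n_timepoints)
                    baseline = 0.1
                    jitter = (
                        rng.normal(0.0, spec.timeseries_jitter, times.size)
                        if spec.timeseries_jitter
                        else np.zeros(times.size)
                    )
                    signals = baseline + k * times + jitter
                    for t, s in zip(times, signals):
                        ts_rows.append(
                            {
                                "population": name,
                                "enzyme": spec.enzyme,
                                "tissue": spec.tissue,
                                "temperature_C": temp,
                                "replicate": rep,
                                "time_min": t,
                                "signal": s,
                            }
                        )
    rates = pd.DataFrame(rate_rows)
    timeseries = pd.DataFrame(ts_rows) if with_timeseries else None
    truth = pd.DataFrame(
        [
            {"population": name, "ea_kj_mol": ea, "pre_exponential": a}
            for name, ea, a in spec.populations
        ]
    )
    return rates, timeseries, truth
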