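"""Two-species spike-in TMT simulation with an injectable notch distortion.

The generator emulates a benchmark in which *S. cerevisiae* peptides are
spiked into *H. sapiens* peptides at 1x / 2x / 6x amounts (5, 10 and 30 ug of
yeast per channel, each channel filled to 100 ug with human peptide), so that
every protein carries a known ground-truth fold change between channel
groups: yeast 2x/1x = 2 and 6x/1x = 6; human 2x/1x = 90/95 and 6x/1x = 70/95.

Per PSM, observed channel intensities are

    obs[c] = 2**(b + s) * [(1 - i) * f_species[c] + i] * 2**eps[c]

where ``b`` is a log-normal protein base abundance, ``s`` a per-PSM
ionization scale, ``f_species`` the species' per-channel mass fraction
(normalized to mean 1), ``i`` the PSM's co-isolation interference fraction
(the background is channel-flat because every channel holds the same total
peptide mass, which is what compresses ratios toward 1), and ``eps``
multiplicative reporter noise. An optional notch distortion then remaps the
log2 intensities (see :func:`apply_notch_artifact`), and low cells may drop
out as missing values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from ._utils import named_streams
from .exceptions import DesignError, ParameterError
from .notch import NotchRegion
from .psm_table import ChannelSet, PSMTable

#: Group contrasts evaluated throughout the benchmark, "numerator_vs_denominator".
DEFAULT_CONTRASTS = ("2x_vs_1x", "6x_vs_1x")

_STAGES = ("proteins", "psms", "interference", "noise", "missing", "quality")


@dataclass(frozen=True)
class MixDesign:
    """Per-channel species masses defining the ground-truth fold changes."""

    channels: ChannelSet
    yeast_mass: tuple[float, ...]
    human_mass: tuple[float, ...]
    total_mass: float

    def __post_init__(self) -> None:
        y = np.asarray(self.yeast_mass, float)
        h = np.asarray(self.human_mass, float)
        if len(y) != len(self.channels) or len(h) != len(self.channels):
            raise DesignError("one mass per channel required for each species")
        if (y <= 0).any() or (h <= 0).any():
            raise DesignError("all per-channel masses must be positive")
        if not np.allclose(y + h, self.total_mass):
            raise DesignError("yeast + human mass must equal total mass in every channel")

    def mass(self, species: str) -> np.ndarray:
        if species == "yeast":
            return np.asarray(self.yeast_mass, float)
        if species == "human":
            return np.asarray(self.human_mass, float)
        raise DesignError(f"unknown species {species!r}")

    def group_mass(self, species: str, group: str) -> float:
        """The (constant) per-channel mass of ``species`` in ``group``."""
        m = self.mass(species)
        idx = [i for i, g in enumerate(self.channels.groups) if g == group]
        if not idx:
            raise DesignError(f"unknown group {group!r}")
        vals = m[idx]
        if not np.allclose(vals, vals[0]):
            raise DesignError(f"{species} mass varies within group {group!r}")
        return float(vals[0])

    def expected_log2fc(self, species: str, contrast: str) -> float:
        """Ground-truth log2 fold change of ``species`` for ``"num_vs_den"``."""
        num, den = parse_contrast(contrast)
        return float(np.log2(self.group_mass(species, num) / self.group_mass(species, den)))

    def fold_changes(self) -> pd.DataFrame:
        """All pairwise group fold changes (>= 1 orientation) for both species."""
        groups = self.channels.group_names
        rows = []
        for sp in ("yeast", "human"):
            for a in groups:
                for b in groups:
                    if a >= b:
                        continue
                    fc = self.group_mass(sp, a) / self.group_mass(sp, b)
                    fc = max(fc, 1.0 / fc)
                    rows.append((sp, a, b, fc))
        return pd.DataFrame(rows, columns=["species", "group_a", "group_b", "fold_change"])

    def min_fold_change(self) -> float:
        """Smallest ground-truth fold change over species and pairwise contrasts."""
        return float(self.fold_changes()["fold_change"].min())


def parse_contrast(contrast: str) -> tuple[str, str]:
    parts = contrast.split("_vs_")
    if len(parts) != 2:
        raise DesignError(f"contrast {contrast!r} must look like 'num_vs_den'")
    return parts[0], parts[1]


def build_mix_design(
    yeast_masses_by_group: Mapping[str, float] | None = None,
    channels: ChannelSet | None = None,
    total_mass: float = 100.0,
) -> MixDesign:
    """Build the spike-in design from per-group yeast masses.

    Defaults reproduce the benchmark: yeast at 5 ug (1x group), 10 ug (2x)
    and 30 ug (6x), each channel made up to 100 ug with human peptide.
    """
    channels = channels or ChannelSet()
    if yeast_masses_by_group is None:
        yeast_masses_by_group = {"1x": 5.0, "2x": 10.0, "6x": 30.0}
    missing = set(channels.group_names) - set(yeast_masses_by_group)
    if missing:
        raise DesignError(f"no yeast mass given for groups: {sorted(missing)}")
    yeast = tuple(float(yeast_masses_by_group[g]) for g in channels.groups)
    for g, m in yeast_masses_by_group.items():
        if m >= total_mass:
            raise DesignError(f"yeast mass {m} in group {g!r} must be below total {total_mass}")
    human = tuple(total_mass - m for m in yeast)
    return MixDesign(channels=channels, yeast_mass=yeast, human_mass=human, total_mass=total_mass)


@dataclass(frozen=True)
class SimParams:
    """Simulation parameters; defaults are the benchmark study conditions.

    All spreads are on the log2 scale. ``interference_dist`` holds Beta
    parameters for the per-PSM co-isolation fraction; the default is skewed
    toward zero, as expected for SPS-MS3 acquisition. ``sn_noise_constant``
    converts mean observed intensity to the "average reporter S/N" metric.
    """

    n_yeast_proteins: int = 300
    n_human_proteins: int = 900
    psm_per_protein: tuple[float, float] = (6.0, 0.5)  # (mean, dispersion), shifted NB, min 1
    psm_redundancy: float = 2.0  # mean PSMs per peptide sequence
    base_mean_log2: float = 10.0
    base_abundance_sd: float = 1.5
    psm_scale_sd: float = 1.5
    reporter_noise_sd: float = 0.4
    #: Beta(a, b) over [0, 1], or a single float for a constant fraction
    interference_dist: tuple[float, float] | float = (0.5, 12.0)
    missing_rate: float = 0.3
    detection_floor_log2: float = 4.0
    notch: NotchRegion | None = field(default_factory=NotchRegion)
    notch_slope: float = 1.5
    delta_cn_dist: tuple[float, float] = (2.0, 2.0)  # Beta(a, b)
    sn_noise_constant: float = 16.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_yeast_proteins <= 0 or self.n_human_proteins <= 0:
            raise ParameterError("protein counts must be positive")
        if self.psm_per_protein[0] < 1 or self.psm_per_protein[1] < 0:
            raise ParameterError("psm_per_protein mean must be >= 1 and dispersion >= 0")
        if self.psm_redundancy < 1:
            raise ParameterError("psm_redundancy must be >= 1")
        for name in ("base_abundance_sd", "psm_scale_sd", "reporter_noise_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if not 0 <= self.missing_rate <= 1:
            raise ParameterError("missing_rate must be in [0, 1]")
        if np.isscalar(self.interference_dist) and not 0 <= self.interference_dist <= 1:
            raise ParameterError("constant interference must be in [0, 1]")
        if self.notch is not None and self.notch_slope <= 0:
            raise ParameterError("notch_slope must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Known species assignments and expected log2 fold changes per contrast."""

    protein_species: dict[str, str]
    peptide_species: dict[str, str]
    expected: dict[tuple[str, str], float]  # (contrast, species) -> log2 fold change
    contrasts: tuple[str, ...] = DEFAULT_CONTRASTS

    def species_of(self, level: str) -> dict[str, str]:
        if level == "protein":
            return self.protein_species
        if level == "peptide":
            return self.peptide_species
        raise ParameterError(f"unknown level {level!r}")

    def expected_log2fc(self, contrast: str, species: str) -> float:
        return self.expected[(contrast, species)]

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        feats = pd.DataFrame(
            [("protein", f, s) for f, s in self.protein_species.items()]
            + [("peptide", f, s) for f, s in self.peptide_species.items()],
            columns=["level", "feature_id", "species"],
        )
        exp = pd.DataFrame(
            [(c, s, v) for (c, s), v in self.expected.items()],
            columns=["contrast", "species", "expected_log2fc"],
        )
        return feats, exp

    @classmethod
    def from_frames(cls, feats: pd.DataFrame, exp: pd.DataFrame) -> "GroundTruth":
        prot = dict(feats.loc[feats["level"] == "protein", ["feature_id", "species"]].itertuples(index=False))
        pep = dict(feats.loc[feats["level"] == "peptide", ["feature_id", "species"]].itertuples(index=False))
        expected = {
            (r.contrast, r.species): float(r.expected_log2fc) for r in exp.itertuples(index=False)
        }
        contrasts = tuple(dict.fromkeys(c for c, _ in expected))
        return cls(protein_species=prot, peptide_species=pep, expected=expected, contrasts=contrasts)


def ground_truth_from_design(
    design: MixDesign,
    protein_species: dict[str, str],
    peptide_species: dict[str, str],
    contrasts: tuple[str, ...] = DEFAULT_CONTRASTS,
) -> GroundTruth:
    expected = {
        (c, sp): design.expected_log2fc(sp, c) for c in contrasts for sp in ("yeast", "human")
    }
    return GroundTruth(
        protein_species=protein_species,
        peptide_species=peptide_species,
        expected=expected,
        contrasts=contrasts,
    )


def apply_notch_artifact(
    x: np.ndarray | float, notch: NotchRegion, slope: float
) -> np.ndarray | float:
    """Distort log2 intensities so the open interval (lower, upper) is depleted.

    Values at or above the upper boundary are unchanged; values below it are
    remapped to ``lower - slope * (upper - x)``. The map is strictly
    increasing on each branch and leaves (lower, upper) empty of outputs.
    With ``slope > 1`` the underestimation grows as intensity decreases.
    """
    if slope <= 0:
        raise ParameterError("notch slope must be positive")
    arr = np.asarray(x, dtype=float)
    out = np.where(arr >= notch.upper, arr, notch.lower - slope * (notch.upper - arr))
    if np.isscalar(x) or arr.ndim == 0:
        return float(out)
    return out


def _shifted_nb(rng: np.random.Generator, n: int, mean: float, dispersion: float) -> np.ndarray:
    """Counts >= 1 with mean ``mean``; NB-like via gamma-Poisson mixing."""
    mu = mean - 1.0
    if mu <= 0:
        return np.ones(n, dtype=int)
    if dispersion <= 0:
        lam = np.full(n, mu)
    else:
        lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion, size=n)
    return 1 + rng.poisson(lam)


def simulate_experiment(design: MixDesign, params: SimParams) -> tuple[PSMTable, GroundTruth]:
    """Simulate a species-annotated PSM table with known ground truth.

    Returns the table (quality metrics filled consistently with the generated
    intensities: ``coisolation_pct = 100 * i``, ``avg_sn`` = mean non-missing
    intensity over ``sn_noise_constant``) and the matching
    :class:`GroundTruth`. Identical parameters, including the seed, yield an
    identical table.
    """
    streams = named_streams(params.seed, _STAGES)
    channels = design.channels
    n_ch = len(channels)

    n_prot = params.n_yeast_proteins + params.n_human_proteins
    species = np.array(["yeast"] * params.n_yeast_proteins + ["human"] * params.n_human_proteins)
    prot_ids = np.array(
        [f"YST{i:05d}" for i in range(params.n_yeast_proteins)]
        + [f"HUM{i:05d}" for i in range(params.n_human_proteins)]
    )
    base = streams["proteins"].normal(params.base_mean_log2, params.base_abundance_sd, n_prot)

    mean_psm, disp = params.psm_per_protein
    n_psm = _shifted_nb(streams["psms"], n_prot, mean_psm, disp)
    prot_idx = np.repeat(np.arange(n_prot), n_psm)
    total_psms = int(n_psm.sum())

    # peptide assignment: each protein's PSMs spread over ~n_psm/redundancy sequences
    pep_of_psm = np.empty(total_psms, dtype=object)
    pos = 0
    for p in range(n_prot):
        k = n_psm[p]
        n_pep = max(1, int(round(k / params.psm_redundancy)))
        assign = streams["psms"].integers(0, n_pep, size=k)
        for j, a in enumerate(assign):
            pep_of_psm[pos + j] = f"{prot_ids[p]}_pep{a:02d}"
        pos += k

    scale = streams["psms"].normal(0.0, params.psm_scale_sd, total_psms)
    if np.isscalar(params.interference_dist):
        interference = np.full(total_psms, float(params.interference_dist))
    else:
        a_i, b_i = params.interference_dist
        interference = streams["interference"].beta(a_i, b_i, total_psms)

    # species mass profiles normalized to mean 1 across channels
    profiles = {
        sp: design.mass(sp) / design.mass(sp).mean() for sp in ("yeast", "human")
    }
    prof = np.vstack([profiles[s] for s in species])[prot_idx]  # (psm, channel)

    mix = (1.0 - interference)[:, None] * prof + interference[:, None]  # flat background = 1
    log2_true = (base[prot_idx] + scale)[:, None] + np.log2(mix)
    eps = streams["noise"].normal(0.0, params.reporter_noise_sd, (total_psms, n_ch))
    log2_obs = log2_true + eps

    if params.notch is not None:
        log2_obs = apply_notch_artifact(log2_obs, params.notch, params.notch_slope)

    obs = np.power(2.0, log2_obs)
    low = log2_obs < params.detection_floor_log2
    drop = low & (streams["missing"].random((total_psms, n_ch)) < params.missing_rate)
    obs[drop] = np.nan

    with np.errstate(invalid="ignore"):
        mean_obs = np.nansum(obs, axis=1) / np.maximum((~np.isnan(obs)).sum(axis=1), 1)
    avg_sn = mean_obs / params.sn_noise_constant
    a_d, b_d = params.delta_cn_dist
    delta_cn = streams["quality"].beta(a_d, b_d, total_psms)

    data = pd.DataFrame(
        {
            "psm_id": [f"psm{i:06d}" for i in range(total_psms)],
            "sequence": pep_of_psm.astype(str),
            "master_proteins": prot_ids[prot_idx],
            "species": species[prot_idx],
            "delta_cn": delta_cn,
            "coisolation_pct": 100.0 * interference,
            "avg_sn": avg_sn,
        }
    )
    for c, label in enumerate(channels.labels):
        data[label] = obs[:, c]

    table = PSMTable(data=data, channels=channels, provenance=f"simulated(seed={params.seed})")
    pep_species = {
        f"{prot_ids[p]}_pep{a:02d}": species[p]
        for p in range(n_prot)
        for a in range(max(1, int(round(n_psm[p] / params.psm_redundancy))))
    }
    truth = ground_truth_from_design(
        design,
        protein_species=dict(zip(prot_ids, species)),
        peptide_species=pep_species,
    )
    return table, truth
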