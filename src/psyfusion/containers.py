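"""In-memory containers shared across the analysis stages.

Conventions
-----------
* BOLD parcel data are ``volumes x regions`` float arrays in arbitrary units.
* EEG data are ``channels x samples`` float arrays in microvolts.
* Connectivity values are Fisher z-transformed Pearson correlations unless a
  function says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical resting-state network labels: the Yeo 7 cortical networks plus
#: one subcortical compartment.
NETWORKS = ("VIS", "SM", "DAN", "SAL", "LIM", "FP", "DMN", "SC")

#: Networks forming the transmodal association pole (high end of the
#: principal cortical gradient).
TRANSMODAL_NETWORKS = ("SAL", "FP", "DMN")

#: Cortical networks used for network-level summaries (subcortex excluded).
CORTICAL_NETWORKS = ("VIS", "SM", "DAN", "SAL", "LIM", "FP", "DMN")


@dataclass
class ParcelTimeSeries:
    """Parcel-level BOLD session: ``volumes x regions`` matrix plus metadata."""

    data: np.ndarray
    tr_seconds: float
    region_labels: list[str]
    subject: str
    condition: str
    injection_index: int
    censor_mask: np.ndarray | None = None  # True = usable volume

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("BOLD data must be volumes x regions")
        if self.data.shape[1] != len(self.region_labels):
            raise ValueError("region_labels length must match data columns")
        if len(set(self.region_labels)) != len(self.region_labels):
            raise ValueError("region_labels must be unique")
        if not 0 <= self.injection_index < self.n_volumes:
            raise ValueError("injection_index outside the scan")
        if self.censor_mask is None:
            self.censor_mask = np.ones(self.n_volumes, dtype=bool)
        else:
            self.censor_mask = np.asarray(self.censor_mask, dtype=bool)
            if self.censor_mask.shape != (self.n_volumes,):
                raise ValueError("censor_mask must have one entry per volume")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Volume acquisition times in seconds from scan start."""
        return np.arange(self.n_volumes) * self.tr_seconds


@dataclass
class NetworkPartition:
    """Region -> network assignment over the 7 Yeo networks + subcortex."""

    region_labels: list[str]
    networks: list[str]

    def __post_init__(self) -> None:
        if len(self.region_labels) != len(self.networks):
            raise ValueError("one network per region required")
        unknown = set(self.networks) - set(NETWORKS)
        if unknown:
            raise ValueError(f"unknown network labels: {sorted(unknown)}")

    def members(self, network: str) -> np.ndarray:
        """Indices of regions assigned to ``network``."""
        return np.flatnonzero(np.asarray(self.networks) == network)

    def indicator(self, networks) -> np.ndarray:
        """Boolean membership vector over regions for a set of networks."""
        nets = set([networks] if isinstance(networks, str) else networks)
        return np.array([n in nets for n in self.networks])

    @property
    def present_networks(self) -> list[str]:
        return [n for n in NETWORKS if n in set(self.networks)]

    def __len__(self) -> int:
        return len(self.region_labels)


@dataclass
class FCMatrix:
    """Symmetric regions x regions Fisher-z connectivity matrix.

    Missing (e.g. zero-variance) regions are NaN; the diagonal carries no
    information and is excluded from every summary.
    """

    values: np.ndarray
    region_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.region_labels)
        if self.values.shape != (n, n):
            raise ValueError("values must be square and match region_labels")

    def offdiag(self) -> np.ndarray:
        """Copy of the matrix with the diagonal masked to NaN."""
        out = self.values.copy()
        np.fill_diagonal(out, np.nan)
        return out


@dataclass
class EEGRecording:
    """Multichannel EEG epoched on a regular 2-s grid."""

    data: np.ndarray  # channels x samples, microvolts
    fs: float
    channel_names: list[str]
    epoch_seconds: float = 2.0
    bad_epochs: set = field(default_factory=set)
    midline_chain: tuple = ("Oz", "POz", "Pz", "Cz", "FCz")
    injection_sample: int = 0
    subject: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(float)
        if self.data.ndim != 2:
            raise ValueError("EEG data must be channels x samples")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError("channel_names length must match data rows")
        if self.n_samples % self.samples_per_epoch:
            raise ValueError("samples must divide into whole epochs")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def samples_per_epoch(self) -> int:
        return int(round(self.epoch_seconds * self.fs))

    @property
    def n_epochs(self) -> int:
        return self.n_samples // self.samples_per_epoch

    def good_epochs(self) -> np.ndarray:
        mask = np.ones(self.n_epochs, dtype=bool)
        for e in self.bad_epochs:
            if 0 <= e < self.n_epochs:
                mask[e] = False
        return mask

    def epoch(self, index: int) -> np.ndarray:
        """channels x samples slice of epoch ``index``."""
        w = self.samples_per_epoch
        return self.data[:, index * w : (index + 1) * w]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in recording") from None


@dataclass
class IntensityTrace:
    """Per-minute subjective drug-intensity ratings (ordinal 0-10).

    ``times`` are minutes relative to the injection; ratings before the
    injection are zero by construction.
    """

    times: np.ndarray
    ratings: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ratings = np.asarray(self.ratings, dtype=float)
        if self.times.shape != self.ratings.shape:
            raise ValueError("times and ratings must align")
        if np.any((self.ratings < 0) | (self.ratings > 10)):
            raise ValueError("ratings must lie in [0, 10]")
        if np.any(self.ratings[self.times < 0] != 0):
            raise ValueError("pre-injection ratings must be zero")


@dataclass
class ReceptorMap:
    """Per-region receptor density in arbitrary nonnegative units."""

    region_labels: list[str]
    density: np.ndarray

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        if self.density.shape != (len(self.region_labels),):
            raise ValueError("one density per region required")
        if not np.all(np.isfinite(self.density)) or np.any(self.density < 0):
            raise ValueError("densities must be finite and nonnegative")


@dataclass
class DynamicFCSeries:
    """Sliding-window connectivity stack: windows x regions x regions."""

    stack: np.ndarray
    window_centers: np.ndarray  # seconds from scan start
    region_labels: list[str]

    def __post_init__(self) -> None:
        self.stack = np.asarray(self.stack, dtype=float)
        self.window_centers = np.asarray(self.window_centers, dtype=float)
        n = len(self.region_labels)
        if self.stack.ndim != 3 or self.stack.shape[1:] != (n, n):
            raise ValueError("stack must be windows x regions x regions")
        if self.stack.shape[0] != self.window_centers.size:
            raise ValueError("one center per window required")
        if np.any(np.diff(self.window_centers) <= 0):
            raise ValueError("window centers must be strictly increasing")

    @property
    def n_windows(self) -> int:
        return self.stack.shape[0]


@dataclass
class GradientSet:
    """Diffusion-embedding scores: units x components, eigenvalue-ordered."""

    scores: np.ndarray
    eigenvalues: np.ndarray
    unit_labels: list[str]
    aligned_to: str | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.scores.ndim != 2:
            raise ValueError("scores must be units x components")
        if self.scores.shape != (len(self.unit_labels), self.eigenvalues.size):
            raise ValueError("scores shape must match labels x eigenvalues")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    @property
    def principal(self) -> np.ndarray:
        """Scores of the first (principal) gradient."""
        return self.scores[:, 0]


@dataclass
class Cluster:
    """One supra-threshold cluster: member units, signed mass, p-value."""

    members: tuple
    mass: float
    p_value: float


@dataclass
class ClusterTestResult:
    """Outcome of a cluster-based permutation test."""

    clusters: list
    t_values: np.ndarray
    threshold: float
    n_permutations: int

    def significant(self, alpha: float = 0.05) -> list:
        return [c for c in self.clusters if c.p_value < alpha]

    @property
    def min_p(self) -> float:
        if not self.clusters:
            return 1.0
        return min(c.p_value for c in self.clusters)
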