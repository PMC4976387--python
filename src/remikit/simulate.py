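"""Synthetic multi-round, multi-channel fluorescence scenes.

Emulates the statistical structure of cyclic immunofluorescence on a
resin-embedded specimen: a field of punctate epitope sites, some clustered
into shared "domains" that induce multi-channel colocalization, labeled
stochastically in each round, with residual signal after elution, a
round-over-round intensity gain (antigen retrieval), rigid inter-round
drift, a smooth low-frequency background, and additive Gaussian noise.

Every draw is controlled by one root seed, split deterministically per
round/channel so any single round can be regenerated on its own.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
import yaml
from scipy.ndimage import gaussian_filter
from scipy.ndimage import shift as ndi_shift

__all__ = [
    "SceneConfig",
    "Scene",
    "generate_scene",
    "draw_labeled_sites",
    "render_round",
    "simulate_dataset",
]

U16_MAX = np.float64(2**16 - 1)

#: σ (px) of the Gaussian scatter of domain-member sites around their
#: domain center.  The domain/raft picture is conceptual; this is the
#: simplest generative stand-in.
DOMAIN_SCATTER_SIGMA = 2.0


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of the synthetic epitope field and its imaging.

    Parameters
    ----------
    image_shape
        (rows, cols) of each rendered image, pixels.
    n_sites
        Number of domain-associated punctate epitope sites (ignored when
        ``n_domains == 0``).
    n_domains
        Number of colocalization domains.  0 disables the shared-domain
        structure entirely.
    channel_affinities
        Per channel c, the probability pi_c that a domain-member site
        carries channel c's epitope.  Length defines the channel count.
    background_site_rate
        Count of independent single-channel sites added *per channel*;
        these carry exactly one channel's epitope and no domain.
    label_prob
        Per-round probability q that an available epitope is actually
        bound by its antibody (stochastic epitope labeling).
    residual_fraction
        Expected fraction of a round's site signal remaining after
        elution; each labeled site survives elution independently with
        this probability.
    round_gain
        Multiplicative amplitude factor per successive round, modelling
        the incidental antigen-retrieval gain.  1.0 disables it.
    psf_sigma
        Gaussian point-spread width, pixels.
    noise_sigma
        Additive Gaussian noise std, intensity units.
    background_amplitude
        Peak-to-trough scale of the smooth low-frequency background.
    drift_per_round
        Rigid (dy, dx) translation applied cumulatively per round, px.
    spot_amplitude
        Integrated intensity of one labeled site before round gain.
    seed
        Root RNG seed; identical seed + config give bit-identical output.
    """

    image_shape: tuple[int, int] = (256, 256)
    n_sites: int = 600
    n_domains: int = 40
    channel_affinities: tuple[float, ...] = (0.8, 0.8, 0.8)
    background_site_rate: int = 100
    label_prob: float = 0.8
    residual_fraction: float = 0.055
    round_gain: float = 1.15
    psf_sigma: float = 1.5
    noise_sigma: float = 4.0
    background_amplitude: float = 30.0
    drift_per_round: tuple[float, float] = (1.0, -0.5)
    spot_amplitude: float = 8000.0
    seed: int = 0

    @property
    def n_channels(self) -> int:
        return len(self.channel_affinities)

    def __post_init__(self) -> None:
        rows, cols = self.image_shape
        if rows <= 0 or cols <= 0:
            raise ValueError(f"image_shape must be positive, got {self.image_shape}")
        for name in ("label_prob",):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 <= self.residual_fraction < 1.0:
            raise ValueError(
                f"residual_fraction must lie in [0, 1), got {self.residual_fraction}"
            )
        if any(not 0.0 <= p <= 1.0 for p in self.channel_affinities):
            raise ValueError(
                f"channel_affinities must lie in [0, 1], got {self.channel_affinities}"
            )
        if not self.channel_affinities:
            raise ValueError("need at least one channel")
        if self.psf_sigma <= 0:
            raise ValueError(f"psf_sigma must be > 0, got {self.psf_sigma}")
        if self.n_sites < 0 or self.n_domains < 0 or self.background_site_rate < 0:
            raise ValueError("site/domain counts must be non-negative")

    def replace(self, **kwargs) -> "SceneConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class Scene:
    """A realized epitope field.

    ``site_positions`` are subpixel (row, col) coordinates, one row per
    site; ``site_channel_membership`` is a boolean (n_sites_total,
    n_channels) matrix; ``domain_assignment`` holds the domain index per
    site, or -1 for independent background sites.
    """

    site_positions: np.ndarray
    site_channel_membership: np.ndarray
    domain_assignment: np.ndarray

    @property
    def n_total_sites(self) -> int:
        return self.site_positions.shape[0]


def generate_scene(config: SceneConfig) -> Scene:
    """Realize the epitope field described by ``config``.

    Domain centers are uniform over the image; each domain site picks a
    domain uniformly and scatters around its center with a Gaussian of
    σ = 2 px.  Channel membership of a domain site is Bernoulli(pi_c)
    per channel, conditionally independent given the domain.  Background
    sites are uniform over the image and belong to exactly one channel.
    """
    rng = np.random.default_rng([config.seed, 0x5CE])
    rows, cols = config.image_shape
    k = config.n_channels

    positions: list[np.ndarray] = []
    membership: list[np.ndarray] = []
    domains: list[np.ndarray] = []

    if config.n_domains > 0 and config.n_sites > 0:
        centers = rng.uniform([0, 0], [rows, cols], size=(config.n_domains, 2))
        assign = rng.integers(0, config.n_domains, size=config.n_sites)
        pos = centers[assign] + rng.normal(0.0, DOMAIN_SCATTER_SIGMA, size=(config.n_sites, 2))
        memb = rng.random((config.n_sites, k)) < np.asarray(config.channel_affinities)
        positions.append(pos)
        membership.append(memb)
        domains.append(assign.astype(np.int64))

    if config.background_site_rate > 0:
        for c in range(k):
            n_bg = config.background_site_rate
            pos = rng.uniform([0, 0], [rows, cols], size=(n_bg, 2))
            memb = np.zeros((n_bg, k), dtype=bool)
            memb[:, c] = True
            positions.append(pos)
            membership.append(memb)
            domains.append(np.full(n_bg, -1, dtype=np.int64))

    if positions:
        site_positions = np.concatenate(positions, axis=0)
        site_membership = np.concatenate(membership, axis=0)
        domain_assignment = np.concatenate(domains, axis=0)
    else:
        site_positions = np.empty((0, 2))
        site_membership = np.empty((0, k), dtype=bool)
        domain_assignment = np.empty(0, dtype=np.int64)

    return Scene(site_positions, site_membership, domain_assignment)


def _splat_sites(shape: tuple[int, int], positions: np.ndarray,
                 amplitudes: np.ndarray) -> np.ndarray:
    """Deposit point masses at subpixel positions by bilinear splatting."""
    img = np.zeros(shape)
    if positions.size == 0:
        return img
    r, c = positions[:, 0], positions[:, 1]
    r0 = np.floor(r).astype(np.int64)
    c0 = np.floor(c).astype(np.int64)
    fr, fc = r - r0, c - c0
    for dr, dc, w in (
        (0, 0, (1 - fr) * (1 - fc)),
        (0, 1, (1 - fr) * fc),
        (1, 0, fr * (1 - fc)),
        (1, 1, fr * fc),
    ):
        rr, cc = r0 + dr, c0 + dc
        ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        np.add.at(img, (rr[ok], cc[ok]), amplitudes[ok] * w[ok])
    return img


def _smooth_background(config: SceneConfig, channel: int) -> np.ndarray:
    """Static per-channel low-frequency background (same in every round)."""
    if config.background_amplitude == 0:
        return np.zeros(config.image_shape)
    rng = np.random.default_rng([config.seed, 0xB6, channel])
    field_ = rng.normal(size=config.image_shape)
    sigma = max(min(config.image_shape) / 8.0, 1.0)
    field_ = gaussian_filter(field_, sigma, mode="reflect")
    span = field_.max() - field_.min()
    if span == 0:
        return np.zeros(config.image_shape)
    return (field_ - field_.min()) / span * config.background_amplitude


def draw_labeled_sites(
    scene: Scene,
    config: SceneConfig,
    round_index: int,
    channel: int,
    post_elution: bool = False,
) -> tuple[np.ndarray, np.random.Generator]:
    """Boolean vector of sites fluorescent in one round/channel.

    Label draws come from the pre-elution stream, so a post-elution image
    retains a subset of the very sites its round labeled, each surviving
    elution independently with probability ``residual_fraction``.  Returns
    the vector and the generator to continue drawing noise from.
    """
    rng_label = np.random.default_rng([config.seed, round_index, channel, 0])
    available = scene.site_channel_membership[:, channel]
    labeled = available & (rng_label.random(scene.n_total_sites)
                           < config.label_prob)
    if not post_elution:
        return labeled, rng_label
    rng = np.random.default_rng([config.seed, round_index, channel, 1])
    labeled = labeled & (rng.random(scene.n_total_sites)
                         < config.residual_fraction)
    return labeled, rng


def render_round(
    scene: Scene,
    config: SceneConfig,
    round_index: int,
    post_elution: bool = False,
) -> np.ndarray:
    """Render one labeling round as an (n_channels, rows, cols) stack.

    Each channel draws its labeled sites independently with probability
    ``label_prob`` among the sites carrying that channel's epitope, renders
    them as Gaussian spots of width ``psf_sigma`` and integrated amplitude
    ``spot_amplitude * round_gain**(round_index - 1)``, applies the
    cumulative rigid drift, and adds the static smooth background plus
    Gaussian noise.  With ``post_elution`` each labeled site survives
    independently with probability ``residual_fraction``, so the expected
    total site signal is that fraction of the labeled round's.

    Pixel values are clipped to the non-negative 16-bit range.
    """
    if round_index < 1:
        raise ValueError(f"round_index must be >= 1, got {round_index}")
    rows, cols = config.image_shape
    gain = config.round_gain ** (round_index - 1)
    drift = np.asarray(config.drift_per_round, dtype=float) * (round_index - 1)
    out = np.empty((config.n_channels, rows, cols))

    for c in range(config.n_channels):
        labeled, rng = draw_labeled_sites(scene, config, round_index, c,
                                          post_elution)
        pos = scene.site_positions[labeled] + drift
        amps = np.full(labeled.sum(), config.spot_amplitude * gain)
        img = _splat_sites((rows, cols), pos, amps)
        img = gaussian_filter(img, config.psf_sigma, mode="constant")
        bg = _smooth_background(config, c)
        if np.any(drift):
            # specimen autofluorescence drifts with the specimen
            bg = ndi_shift(bg, drift, order=1, mode="nearest")
        img += bg
        if config.noise_sigma > 0:
            img += rng.normal(0.0, config.noise_sigma, size=(rows, cols))
        out[c] = np.clip(img, 0.0, U16_MAX)
    return out


def simulate_dataset(
    config: SceneConfig,
    n_rounds: int,
    out_dir: str | Path,
    channel_labels: Sequence[str] | None = None,
    include_post_elution: bool = False,
) -> Path:
    """Render ``n_rounds`` rounds to disk in the package's exchange layout.

    Writes one multi-page 16-bit grayscale TIFF per round (one page per
    channel), a tab-separated ``manifest.tsv`` (file, page, round, channel,
    label) and a human-readable ``config.yaml`` echo.  Post-elution images,
    if requested, are stored as extra pseudo-channels named
    ``<channel>_posteluted`` within each round's file.

    Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if channel_labels is None:
        channel_labels = [f"ch{c}" for c in range(config.n_channels)]
    if len(channel_labels) != config.n_channels:
        raise ValueError("channel_labels length must match channel count")

    scene = generate_scene(config)
    rows = []
    for r in range(1, n_rounds + 1):
        stack = render_round(scene, config, r)
        pages = [np.round(stack[c]).astype(np.uint16) for c in range(config.n_channels)]
        names = list(channel_labels)
        if include_post_elution:
            post = render_round(scene, config, r, post_elution=True)
            pages += [np.round(post[c]).astype(np.uint16) for c in range(config.n_channels)]
            names += [f"{lbl}_posteluted" for lbl in channel_labels]
        fname = f"round{r:02d}.tif"
        tifffile.imwrite(out_dir / fname, np.stack(pages),
                     photometric='minisblack')
        for page, name in enumerate(names):
            rows.append((fname, page, r, name, name))

    manifest = out_dir / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("file\tpage\tround\tchannel\tlabel\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")

    echo = {f.name: getattr(config, f.name) for f in dataclasses.fields(config)}
    echo = {k: (list(v) if isinstance(v, tuple) else v) for k, v in echo.items()}
    echo["n_rounds"] = n_rounds
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(echo, fh, sort_keys=False)
    return manifest
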