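"""Log-Gabor filter bank and block-mean texture features.

Texture is the primary morphological signal that separates embryonic
stages: the overall shape of the embryo changes slowly, while local texture
(cell size, furrows, germ-band position) changes with developmental time.
Log-Gabor filters capture this with joint spatial/frequency localization and,
unlike plain Gabor filters, have exactly zero DC response, so a constant
intensity offset contributes nothing to the features.

In the 2-D frequency plane (polar coordinates, radius ``r`` in cycles/pixel
and angle ``theta``) a log-Gabor transfer function is

    G(r, theta) = exp(-log(r / f0)^2 / (2 log(sigma_f)^2))
                * exp(-d(theta, theta0)^2 / (2 sigma_theta^2))

where ``f0`` is the centre frequency, ``theta0`` the filter orientation,
``sigma_f`` the ratio sigma_r/f0 fixing the (scale-invariant) radial
bandwidth and ``d`` the wrap-around angular distance.  The default bank uses
4 scales x 6 orientations = 24 filters.

An image is filtered in the frequency domain; the magnitude of each complex
response ("Gabor image") is downsampled by 8 x 8 block means, giving
16 x 40 = 640 values per filter and a 24 x 640 = 15 360-dimensional feature
vector per standardized 128 x 320 image.  Feature index ``g * 640 + b``
holds the response of Gabor image ``g`` (scale-major, then orientation) on
sub-block ``b`` (row-major).  The 24 features that describe one image
region form a natural group, which is what the group-sparse learners
exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image_io import EmbryoImage, ImageValidationError, STANDARD_SHAPE

DEFAULT_N_SCALES = 4
DEFAULT_N_ORIENTATIONS = 6
DEFAULT_MIN_WAVELENGTH = 3.0
DEFAULT_SCALE_MULTIPLIER = 2.1
DEFAULT_SIGMA_ON_F = 0.55
DEFAULT_THETA_SIGMA_RATIO = 0.66
DEFAULT_BLOCK = 8


def log_gabor_value(
    r: np.ndarray | float,
    theta: np.ndarray | float,
    f0: float,
    theta0: float,
    sigma_on_f: float,
    theta_sigma: float,
) -> np.ndarray | float:
    """Evaluate the log-Gabor transfer function at polar frequency (r, theta).

    Defined for r > 0; the DC point (r = 0) is handled separately by the
    bank constructor (forced to zero).  The maximum value 1 is attained at
    ``r = f0, theta = theta0``.
    """
    r = np.asarray(r, dtype=float)
    radial = np.exp(-(np.log(r / f0) ** 2) / (2.0 * np.log(sigma_on_f) ** 2))
    dtheta = np.arctan2(np.sin(theta - theta0), np.cos(theta - theta0))
    angular = np.exp(-(dtheta**2) / (2.0 * theta_sigma**2))
    return radial * angular


@dataclass(frozen=True)
class LogGaborFilterBank:
    """A fixed set of log-Gabor transfer functions over one image geometry.

    ``transfer_functions`` has shape (n_scales * n_orientations, height,
    width) in FFT layout (DC at index [0, 0]), ordered scale-major then
    orientation: filter ``s * n_orientations + o`` has centre frequency
    ``center_frequencies[s]`` and orientation ``o * pi / n_orientations``.
    """

    height: int
    width: int
    n_scales: int
    n_orientations: int
    center_frequencies: tuple[float, ...]
    sigma_on_f: float
    theta_sigma: float
    transfer_functions: np.ndarray = field(repr=False)

    @property
    def n_filters(self) -> int:
        return self.n_scales * self.n_orientations

    def orientation(self, o: int) -> float:
        return o * np.pi / self.n_orientations

    def params_dict(self) -> dict:
        """Bank parameters as a JSON-serializable dict (for sidecar files)."""
        return {
            "height": self.height,
            "width": self.width,
            "n_scales": self.n_scales,
            "n_orientations": self.n_orientations,
            "center_frequencies": list(self.center_frequencies),
            "sigma_on_f": self.sigma_on_f,
            "theta_sigma": self.theta_sigma,
            "feature_order": "feature index = gabor_index * n_blocks + block_index; "
            "gabor_index = scale * n_orientations + orientation; blocks row-major",
        }


@dataclass(frozen=True)
class GaborImage:
    """Magnitude of one complex log-Gabor response, same size as the input."""

    magnitudes: np.ndarray
    scale_index: int
    orientation_index: int


@dataclass(frozen=True)
class GroupStructure:
    """Partition of feature indices into disjoint groups (one per region).

    For the standard layout there are 640 groups of 24 features: group ``b``
    collects, across all 24 Gabor images, the feature computed on image
    sub-block ``b``.
    """

    groups: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        all_idx = np.concatenate([np.asarray(g, dtype=int) for g in self.groups])
        if len(np.unique(all_idx)) != all_idx.size:
            raise ValueError("group structure has overlapping groups")
        expected = np.arange(all_idx.size)
        if not np.array_equal(np.sort(all_idx), expected):
            raise ValueError("groups must exactly cover indices 0..d-1")
        object.__setattr__(
            self, "groups", tuple(np.asarray(g, dtype=int) for g in self.groups)
        )

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def n_features(self) -> int:
        return sum(g.size for g in self.groups)

    @property
    def group_ids(self) -> np.ndarray:
        """Group id per feature index (vectorized form of the partition)."""
        ids = np.empty(self.n_features, dtype=int)
        for gi, g in enumerate(self.groups):
            ids[g] = gi
        return ids


def feature_group_structure(n_gabor_images: int, n_blocks: int) -> GroupStructure:
    """The region-wise grouping for the standard feature layout.

    Feature ``g * n_blocks + b`` belongs to group ``b``.
    """
    base = np.arange(n_gabor_images) * n_blocks
    return GroupStructure(groups=tuple(base + b for b in range(n_blocks)))


def build_filter_bank(
    height: int = STANDARD_SHAPE[0],
    width: int = STANDARD_SHAPE[1],
    n_scales: int = DEFAULT_N_SCALES,
    n_orientations: int = DEFAULT_N_ORIENTATIONS,
    min_wavelength: float = DEFAULT_MIN_WAVELENGTH,
    scale_multiplier: float = DEFAULT_SCALE_MULTIPLIER,
    sigma_on_f: float = DEFAULT_SIGMA_ON_F,
    theta_sigma_ratio: float = DEFAULT_THETA_SIGMA_RATIO,
) -> LogGaborFilterBank:
    """Construct the log-Gabor bank for a given image geometry.

    Scale ``s`` has centre frequency ``1 / (min_wavelength *
    scale_multiplier**s)`` cycles/pixel; orientation ``o`` points along
    ``o * pi / n_orientations``.  ``theta_sigma_ratio`` sets the angular
    standard deviation as a fraction of the orientation spacing.
    """
    if n_scales < 1 or n_orientations < 1:
        raise ValueError("need at least one scale and one orientation")
    if min_wavelength < 2:
        raise ValueError(
            f"min_wavelength must be >= 2 pixels (Nyquist), got {min_wavelength}"
        )
    fy = np.fft.fftfreq(height)[:, None]
    fx = np.fft.fftfreq(width)[None, :]
    r = np.hypot(fx, fy)
    theta = np.arctan2(fy, fx)
    r_safe = r.copy()
    r_safe[0, 0] = 1.0  # placeholder; DC forced to zero below

    theta_sigma = theta_sigma_ratio * np.pi / n_orientations
    freqs = tuple(
        1.0 / (min_wavelength * scale_multiplier**s) for s in range(n_scales)
    )
    transfer = np.empty((n_scales * n_orientations, height, width))
    for s, f0 in enumerate(freqs):
        for o in range(n_orientations):
            theta0 = o * np.pi / n_orientations
            g = log_gabor_value(r_safe, theta, f0, theta0, sigma_on_f, theta_sigma)
            g[0, 0] = 0.0
            transfer[s * n_orientations + o] = g
    return LogGaborFilterBank(
        height=height,
        width=width,
        n_scales=n_scales,
        n_orientations=n_orientations,
        center_frequencies=freqs,
        sigma_on_f=sigma_on_f,
        theta_sigma=theta_sigma,
        transfer_functions=transfer,
    )


def apply_filter_bank(
    image: EmbryoImage | np.ndarray, bank: LogGaborFilterBank
) -> list[GaborImage]:
    """Filter an image with every transfer function of the bank.

    Filtering happens in the frequency domain (circular boundary); each
    output is the pixelwise magnitude of the complex response.  Order is
    scale-major, then orientation.
    """
    px = image.pixels if isinstance(image, EmbryoImage) else np.asarray(image, dtype=float)
    if px.shape != (bank.height, bank.width):
        raise ImageValidationError(
            f"image shape {px.shape} does not match bank geometry "
            f"({bank.height}, {bank.width})"
        )
    spectrum = np.fft.fft2(px)
    out = []
    for idx in range(bank.n_filters):
        response = np.fft.ifft2(spectrum * bank.transfer_functions[idx])
        out.append(
            GaborImage(
                magnitudes=np.abs(response),
                scale_index=idx // bank.n_orientations,
                orientation_index=idx % bank.n_orientations,
            )
        )
    return out


def block_mean_downsample(
    gabor: GaborImage | np.ndarray, block: int = DEFAULT_BLOCK
) -> np.ndarray:
    """Mean over non-overlapping ``block x block`` sub-blocks, row-major.

    A 128 x 320 input with block 8 yields 16 x 40 = 640 values.
    """
    arr = gabor.magnitudes if isinstance(gabor, GaborImage) else np.asarray(gabor, dtype=float)
    h, w = arr.shape
    if h % block or w % block:
        raise ImageValidationError(
            f"image dimensions {arr.shape} not divisible by block size {block}"
        )
    return arr.reshape(h // block, block, w // block, block).mean(axis=(1, 3)).ravel()


def extract_features(
    image: EmbryoImage | np.ndarray,
    bank: LogGaborFilterBank | None = None,
    block: int = DEFAULT_BLOCK,
) -> tuple[np.ndarray, GroupStructure]:
    """Full texture feature vector and its region-group structure.

    Returns a float vector of dimension ``n_filters * n_blocks`` (15 360 for
    the standard geometry) ordered ``gabor_index * n_blocks + block_index``,
    and the :class:`GroupStructure` partitioning it into one group of
    ``n_filters`` features per image region.
    """
    if bank is None:
        px = image.pixels if isinstance(image, EmbryoImage) else np.asarray(image)
        bank = build_filter_bank(height=px.shape[0], width=px.shape[1])
    gabor_images = apply_filter_bank(image, bank)
    blocks = [block_mean_downsample(g, block) for g in gabor_images]
    n_blocks = blocks[0].size
    features = np.concatenate(blocks)
    return features, feature_group_structure(len(gabor_images), n_blocks)


def extract_feature_matrix(
    images: list[EmbryoImage] | np.ndarray,
    bank: LogGaborFilterBank | None = None,
    block: int = DEFAULT_BLOCK,
) -> tuple[np.ndarray, GroupStructure]:
    """Stack :func:`extract_features` over a corpus into an (n, d) matrix."""
    if len(images) == 0:
        raise ValueError("empty image list")
    if bank is None:
        first = images[0]
        px = first.pixels if isinstance(first, EmbryoImage) else np.asarray(first)
        bank = build_filter_bank(height=px.shape[0], width=px.shape[1])
    rows = []
    groups = None
    for img in images:
        vec, groups = extract_features(img, bank, block)
        rows.append(vec)
    return np.vstack(rows), groups
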