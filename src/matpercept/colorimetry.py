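"""Image colorimetry: CIELab grayscale, LCh channels, u'v' saturation.

All operations take 8-bit sRGB arrays (H x W x 3, uint8) and assume the D65
white point.  L* uses the CIE [0, 100] scale; 8-bit gray output maps
L*/100*255 with half-up rounding (the convention of 8-bit Lab pipelines).
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from .core_data import DomainError, ParameterError


class ImageFormatError(ValueError):
    """Input raster is not 8-bit RGB."""


class DegeneracyError(ValueError):
    """Masked statistics are degenerate (zero variance)."""


# sRGB <-> XYZ (D65, IEC 61966-2-1)
_M_RGB2XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
_M_XYZ2RGB = np.linalg.inv(_M_RGB2XYZ)

_D65_XYZ = np.array([0.95047, 1.0, 1.08883])


def _uv_prime(xyz: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X, Y, Z = xyz[..., 0], xyz[..., 1], xyz[..., 2]
    denom = X + 15.0 * Y + 3.0 * Z
    safe = denom > 0
    u = np.where(safe, 4.0 * X / np.where(safe, denom, 1.0), WHITE_U)
    v = np.where(safe, 9.0 * Y / np.where(safe, denom, 1.0), WHITE_V)
    return u, v


_wd = _D65_XYZ[0] + 15.0 * _D65_XYZ[1] + 3.0 * _D65_XYZ[2]
WHITE_U = 4.0 * _D65_XYZ[0] / _wd
WHITE_V = 9.0 * _D65_XYZ[1] / _wd


def round_half_up(values: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(values) + 0.5)


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3 or image.dtype != np.uint8:
        raise ImageFormatError("expected an 8-bit RGB image (H x W x 3, uint8)")
    return image


def srgb_decode(image_u8: np.ndarray) -> np.ndarray:
    """8-bit sRGB -> linear RGB in [0, 1]."""
    c = image_u8.astype(float) / 255.0
    return np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)


def srgb_encode(linear: np.ndarray) -> np.ndarray:
    """Linear RGB in [0, 1] -> 8-bit sRGB with half-up rounding."""
    linear = np.clip(linear, 0.0, 1.0)
    c = np.where(
        linear <= 0.0031308, 12.92 * linear, 1.055 * linear ** (1 / 2.4) - 0.055
    )
    return round_half_up(c * 255.0).astype(np.uint8)


def rgb_to_xyz(image_u8: np.ndarray) -> np.ndarray:
    return srgb_decode(image_u8) @ _M_RGB2XYZ.T


@dataclasses.dataclass(frozen=True)
class LabImage:
    """Per-pixel CIELab representation (D65) of an sRGB image."""

    L: np.ndarray      # [0, 100]
    a: np.ndarray
    b: np.ndarray

    @property
    def chroma(self) -> np.ndarray:
        return np.hypot(self.a, self.b)

    @property
    def hue(self) -> np.ndarray:
        return np.degrees(np.arctan2(self.b, self.a)) % 360.0


def to_lab(image: np.ndarray) -> LabImage:
    xyz = rgb_to_xyz(_check_rgb(image))
    t = xyz / _D65_XYZ
    delta = 6.0 / 29.0
    f = np.where(t > delta**3, np.cbrt(t), t / (3 * delta**2) + 4.0 / 29.0)
    L = 116.0 * f[..., 1] - 16.0
    a = 500.0 * (f[..., 0] - f[..., 1])
    b = 200.0 * (f[..., 1] - f[..., 2])
    return LabImage(L, a, b)


def to_grayscale_lightness(image: np.ndarray) -> np.ndarray:
    """Decolorize via CIELab L*: gray value = round(L*/100*255), 3 channels."""
    lab = to_lab(image)
    gray = round_half_up(lab.L / 100.0 * 255.0).astype(np.uint8)
    return np.repeat(gray[..., None], 3, axis=2)


@dataclasses.dataclass(frozen=True)
class LCHResult:
    lightness: np.ndarray       # uint8, L*/100*255
    chroma: np.ndarray          # uint8, C* rescaled over the image max
    lightness_raw: np.ndarray   # L* in [0, 100]
    chroma_raw: np.ndarray      # C* unscaled
    chroma_scale: float         # the max C* used for rescaling


def extract_lch(image: np.ndarray) -> LCHResult:
    """CIELCh Lightness and Chroma channels as separate 8-bit rasters."""
    lab = to_lab(image)
    chroma = lab.chroma
    cmax = float(chroma.max())
    if cmax < 1e-3:  # numerically achromatic: don't blow up rounding noise
        cmax = 0.0
    scaled = chroma / cmax * 255.0 if cmax > 0 else np.zeros_like(chroma)
    return LCHResult(
        round_half_up(lab.L / 100.0 * 255.0).astype(np.uint8),
        round_half_up(scaled).astype(np.uint8),
        lab.L,
        chroma,
        cmax,
    )


@dataclasses.dataclass(frozen=True)
class SaturationMap:
    """Per-pixel CIE u'v' saturation 13*sqrt((u'-u'_n)^2+(v'-v'_n)^2) and Y."""

    saturation: np.ndarray
    luminance: np.ndarray
    r: float
    r_defined: bool


def saturation_of(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(u'v' saturation, relative luminance Y) per pixel."""
    xyz = rgb_to_xyz(_check_rgb(image))
    u, v = _uv_prime(xyz)
    s = 13.0 * np.hypot(u - WHITE_U, v - WHITE_V)
    return s, xyz[..., 1]


def saturation_luminance(image: np.ndarray, mask: Optional[np.ndarray] = None) -> SaturationMap:
    """Saturation map plus the Pearson r of (s, Y) over the masked pixels."""
    s, Y = saturation_of(image)
    if mask is None:
        mask = np.ones(s.shape, dtype=bool)
    if mask.shape != s.shape:
        raise ParameterError("mask shape must match image")
    sm, Ym = s[mask], Y[mask]
    if sm.size < 2:
        raise DomainError("mask must select at least 2 pixels")
    defined = sm.std() > 0 and Ym.std() > 0
    r = float(np.corrcoef(sm, Ym)[0, 1]) if defined else float("nan")
    return SaturationMap(s, Y, r, defined)


@dataclasses.dataclass(frozen=True)
class BlendResult:
    image: np.ndarray                # uint8 output
    saturation_in: np.ndarray        # masked input saturation (1-D)
    saturation_blended: np.ndarray   # pre-clip target saturation (1-D)
    saturation_applied: np.ndarray   # post zero-clip (1-D)
    mu_s: float
    sigma_s: float
    w: float
    r_preclip: float                 # Pearson r(s_blended, Y) over mask
    gamut_clip_fraction: float


def blend_saturation(
    image: np.ndarray, w: float, mask: Optional[np.ndarray] = None
) -> BlendResult:
    """Push pixel saturation toward the luminance distribution.

    Within the mask, saturation s and luminance Y are z-normalized and
    blended, z_out = (1-w) z(s) + w z(Y), re-standardized, and mapped back
    through the original saturation mean and SD (clipped at 0).  Hue angle
    and luminance are unchanged: chromaticity moves radially in the u'v'
    plane relative to the D65 white point.  Results outside the sRGB gamut
    are pulled back toward the white point along the same ray and flagged.
    """
    image = _check_rgb(image)
    if not 0.0 <= w <= 1.0:
        raise ParameterError(f"blend weight {w} outside [0, 1]")
    if mask is None:
        mask = np.ones(image.shape[:2], dtype=bool)
    if mask.shape != image.shape[:2]:
        raise ParameterError("mask shape must match image")
    xyz = rgb_to_xyz(image)
    u, v = _uv_prime(xyz)
    Y = xyz[..., 1]
    s = 13.0 * np.hypot(u - WHITE_U, v - WHITE_V)

    sm, Ym = s[mask], Y[mask]
    mu_s, sigma_s = float(sm.mean()), float(sm.std())
    if sigma_s == 0:
        raise DegeneracyError("masked saturation has zero variance")
    if Ym.std() == 0:
        raise DegeneracyError("masked luminance has zero variance")
    z_s = (sm - mu_s) / sigma_s
    z_y = (Ym - Ym.mean()) / Ym.std()
    z_out = (1.0 - w) * z_s + w * z_y
    z_std = z_out.std()
    if z_std > 0:
        z_out = (z_out - z_out.mean()) / z_std
    s_blend = mu_s + sigma_s * z_out
    s_applied = np.clip(s_blend, 0.0, None)
    r_pre = float(np.corrcoef(s_blend, Ym)[0, 1]) if s_blend.std() > 0 else float("nan")

    # radial chromaticity reconstruction
    du, dv = (u[mask] - WHITE_U), (v[mask] - WHITE_V)
    radius = np.hypot(du, dv)
    safe = radius > 1e-12
    ratio = np.where(safe, np.where(safe, s_applied, 0.0) / np.where(safe, 13.0 * radius, 1.0), 0.0)
    u_new = WHITE_U + du * ratio
    v_new = WHITE_V + dv * ratio

    def uv_to_linear(uu, vv, yy):
        with np.errstate(divide="ignore", invalid="ignore"):
            X = yy * 9.0 * uu / (4.0 * vv)
            Z = yy * (12.0 - 3.0 * uu - 20.0 * vv) / (4.0 * vv)
        X = np.where(vv > 0, X, 0.0)
        Z = np.where(vv > 0, Z, 0.0)
        return np.stack([X, yy, Z], axis=-1) @ _M_XYZ2RGB.T

    linear = uv_to_linear(u_new, v_new, Ym)
    tol = 1e-9
    out_of_gamut = ((linear < -tol) | (linear > 1 + tol)).any(axis=-1)
    clip_fraction = float(out_of_gamut.mean())
    if out_of_gamut.any():
        # bisect a chroma scale k in [0,1] toward the white point per pixel
        idx = np.where(out_of_gamut)[0]
        lo = np.zeros(idx.size)
        hi = np.ones(idx.size)
        for _ in range(40):
            mid = (lo + hi) / 2.0
            uu = WHITE_U + (u_new[idx] - WHITE_U) * mid
            vv = WHITE_V + (v_new[idx] - WHITE_V) * mid
            lin = uv_to_linear(uu, vv, Ym[idx])
            ok = ((lin >= -tol) & (lin <= 1 + tol)).all(axis=-1)
            lo = np.where(ok, mid, lo)
            hi = np.where(ok, hi, mid)
        u_new[idx] = WHITE_U + (u_new[idx] - WHITE_U) * lo
        v_new[idx] = WHITE_V + (v_new[idx] - WHITE_V) * lo
        linear[idx] = uv_to_linear(u_new[idx], v_new[idx], Ym[idx])

    out = image.copy()
    out[mask] = srgb_encode(linear)
    return BlendResult(
        out, sm, s_blend, s_applied, mu_s, sigma_s, float(w), r_pre, clip_fraction
    )
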