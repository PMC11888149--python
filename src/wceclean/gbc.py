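"""Two-class tri-variate Gaussian Bayes classifier over RGB pixels.

Each pixel is an observation x = (r, g, b) on the raw 0-255 intensity
scale.  For each class k in {clean, contaminated} the class-conditional
density is modelled as a full-covariance tri-variate Gaussian

    p(x | y=k) = N(x; mu_k, Sigma_k),

with mu_k the sample mean, Sigma_k the (unbiased) sample covariance of the
training pixels of class k, and the prior p(y=k) the training pixel share
of class k.  A pixel is assigned to the class maximising the posterior
p(y=k | x) ∝ p(x | y=k) p(y=k); the evidence is computed (not dropped) so
the returned posterior map is a true probability usable for AUROC.

The model has 26 learned numbers: 2 priors + 2 x (3 mean + 9 covariance).

All likelihood math runs in log space through a Cholesky factorisation of
Sigma_k + eps*I; the explicit inverse and determinant are never formed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.special import logsumexp

from .image_io import validate_image, validate_mask

__all__ = [
    "FitError",
    "ModelFormatError",
    "ClassModel",
    "GbcModel",
    "extract_class_pixels",
    "fit",
    "log_likelihood",
    "posterior",
    "segment",
    "clean_fraction",
    "parameter_count",
    "save_model",
    "load_model",
]

_D = 3  # RGB
_LOG_2PI = float(np.log(2.0 * np.pi))


class FitError(RuntimeError):
    """Raised when the training annotation cannot identify both classes."""


class ModelFormatError(ValueError):
    """Raised when a serialized model violates the schema or its invariants."""


@dataclass(frozen=True)
class ClassModel:
    """Gaussian model of one class: mean (3,), covariance (3, 3), prior, N_k.

    ``covariance`` is the regularised matrix actually used for inference
    (already includes the eps*I ridge).
    """

    mean: np.ndarray
    covariance: np.ndarray
    prior: float
    n_pixels: int
    _chol_lower: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float).reshape(_D)
        cov = np.asarray(self.covariance, dtype=float).reshape(_D, _D)
        if not np.allclose(cov, cov.T, atol=1e-9):
            raise ModelFormatError("covariance is not symmetric")
        if not 0.0 <= self.prior <= 1.0:
            raise ModelFormatError(f"prior {self.prior} outside [0, 1]")
        try:
            low = cholesky(cov, lower=True)
        except np.linalg.LinAlgError as exc:
            raise ModelFormatError("covariance is not positive definite") from exc
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "covariance", cov)
        object.__setattr__(self, "_chol_lower", low)

    @property
    def log_det(self) -> float:
        return 2.0 * float(np.log(np.diag(self._chol_lower)).sum())


@dataclass(frozen=True)
class GbcModel:
    """Fitted two-class Gaussian Bayes classifier (26 learned parameters)."""

    clean: ClassModel
    contaminated: ClassModel
    regularization_epsilon: float = 1e-3
    fit_seed: int | None = None
    source_images: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        total = self.clean.prior + self.contaminated.prior
        if abs(total - 1.0) > 1e-12:
            raise ModelFormatError(f"class priors sum to {total}, expected 1")


def extract_class_pixels(
    images: list[np.ndarray],
    masks: list[np.ndarray],
    label: str,
    fov: np.ndarray | None = None,
) -> np.ndarray:
    """Concatenate the RGB values of all pixels of one class into an N_k x 3 matrix.

    Rows follow row-major pixel order within each frame, frames in list
    order, so the extraction is reproducible.  ``label`` is ``"clean"``
    (mask True) or ``"contaminated"`` (mask False).
    """
    if label not in ("clean", "contaminated"):
        raise ValueError(f"label must be 'clean' or 'contaminated', got {label!r}")
    if len(images) != len(masks):
        raise ValueError("images and masks differ in length")
    want = label == "clean"
    rows = []
    for img, msk in zip(images, masks):
        img = validate_image(img)
        msk = validate_mask(msk, img.shape[:2])
        sel = msk if want else ~msk
        if fov is not None:
            sel = sel & np.asarray(fov, dtype=bool)
        rows.append(img[sel].astype(np.float64))
    matrix = np.concatenate(rows, axis=0) if rows else np.empty((0, _D))
    if matrix.shape[0] == 0:
        raise FitError(f"class {label!r} absent from training annotation")
    return matrix


def fit(
    images: list[np.ndarray],
    masks: list[np.ndarray],
    epsilon: float = 1e-3,
    fov: np.ndarray | None = None,
    unbiased: bool = True,
    fit_seed: int | None = None,
    source_images: tuple[str, ...] = (),
) -> GbcModel:
    """Fit priors, class means and full covariances from annotated frames.

    prior_k = N_k / (N_clean + N_cont); mean_k is the column average of the
    class pixel matrix; Sigma_k is the sample covariance (unbiased 1/(N-1)
    by default, biased 1/N with ``unbiased=False``) plus an ``epsilon * I``
    ridge guaranteeing positive definiteness on degenerate annotations.
    """
    per_class = {}
    counts = {}
    for label in ("clean", "contaminated"):
        x = extract_class_pixels(images, masks, label, fov=fov)
        if x.shape[0] < 4:
            raise FitError(f"class {label!r} has only {x.shape[0]} pixels; covariance unidentifiable")
        if not np.isfinite(x).all():
            raise ValueError("non-finite pixel intensities in training data")
        counts[label] = x.shape[0]
        per_class[label] = x
    total = sum(counts.values())
    models = {}
    for label, x in per_class.items():
        mean = x.mean(axis=0)
        cov = np.cov(x, rowvar=False, ddof=1 if unbiased else 0)
        cov = cov + epsilon * np.eye(_D)
        models[label] = ClassModel(
            mean=mean, covariance=cov, prior=counts[label] / total, n_pixels=counts[label]
        )
    return GbcModel(
        clean=models["clean"],
        contaminated=models["contaminated"],
        regularization_epsilon=epsilon,
        fit_seed=fit_seed,
        source_images=tuple(source_images),
    )


def _log_likelihood_rows(x: np.ndarray, cm: ClassModel) -> np.ndarray:
    """Gaussian log-density of each row of an N x 3 matrix under one class."""
    diff = x - cm.mean
    # solve L z = diff^T; the quadratic form is ||z||^2
    z = cho_solve((cm._chol_lower, True), diff.T, check_finite=False)
    quad = np.einsum("ij,ji->i", diff, z)
    return -0.5 * (_D * _LOG_2PI + cm.log_det + quad)


def log_likelihood(x: np.ndarray, cm: ClassModel) -> float:
    """Log of the tri-variate Gaussian density N(x; mu_k, Sigma_k).

    Computed via the stored Cholesky factor; never forms the explicit
    inverse or determinant of Sigma.
    """
    x = np.asarray(x, dtype=float).reshape(1, _D)
    if not np.isfinite(x).all():
        raise ValueError("non-finite observation")
    return float(_log_likelihood_rows(x, cm)[0])


def _log_joint(x: np.ndarray, model: GbcModel) -> np.ndarray:
    """N x 2 matrix of log prior + log likelihood, columns (clean, contaminated)."""
    with np.errstate(divide="ignore"):  # a zero prior is a legal hard exclusion
        lp = np.array([np.log(model.clean.prior), np.log(model.contaminated.prior)])
    return np.stack(
        [
            lp[0] + _log_likelihood_rows(x, model.clean),
            lp[1] + _log_likelihood_rows(x, model.contaminated),
        ],
        axis=1,
    )


def posterior(x: np.ndarray, model: GbcModel) -> tuple[float, float]:
    """Posterior class probabilities (p_clean, p_contaminated) for one pixel.

    Normalised through log-sum-exp, so the pair sums to 1 and the evidence
    p(x) is handled implicitly.
    """
    x = np.asarray(x, dtype=float).reshape(1, _D)
    joint = _log_joint(x, model)
    post = np.exp(joint - logsumexp(joint, axis=1, keepdims=True))[0]
    return float(post[0]), float(post[1])


def segment(
    image: np.ndarray,
    model: GbcModel,
    fov: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Classify every pixel of a frame; returns (clean mask, p_clean map).

    The mask holds the per-pixel posterior argmax (ties label clean, keeping
    the emphasised sensitivity toward the positive class); the map holds
    p(clean | x) in [0, 1].  Pixels outside ``fov`` are labelled
    contaminated with p_clean = 0.
    """
    image = validate_image(image)
    h, w = image.shape[:2]
    x = image.reshape(-1, _D).astype(np.float64)
    joint = _log_joint(x, model)
    p_clean = np.exp(joint[:, 0] - logsumexp(joint, axis=1)).reshape(h, w)
    labels = (joint[:, 0] >= joint[:, 1]).reshape(h, w)
    if fov is not None:
        fov = np.asarray(fov, dtype=bool)
        labels = labels & fov
        p_clean = np.where(fov, p_clean, 0.0)
    return labels, p_clean


def clean_fraction(mask: np.ndarray, fov: np.ndarray | None = None) -> float:
    """Fraction of (in-FOV) pixels labelled clean — the visualisation-quality score."""
    mask = validate_mask(mask)
    if fov is not None:
        fov = np.asarray(fov, dtype=bool)
        n = int(fov.sum())
        if n == 0:
            raise ValueError("field of view contains no pixels")
        return float(mask[fov].sum()) / n
    return float(mask.mean())


def parameter_count(model: GbcModel) -> int:
    """Number of learned parameters actually stored by the serializer."""
    return sum(len(v) for v in _learned_parameters(model).values())


def _learned_parameters(model: GbcModel) -> dict[str, list[float]]:
    out = {}
    for name, cm in (("clean", model.clean), ("contaminated", model.contaminated)):
        out[f"{name}.prior"] = [float(cm.prior)]
        out[f"{name}.mean"] = [float(v) for v in cm.mean]
        out[f"{name}.covariance"] = [float(v) for v in cm.covariance.ravel()]
    return out


def save_model(model: GbcModel, path: str | Path) -> None:
    """Serialize the 26 learned parameters plus fit metadata as JSON."""
    payload = {
        "format": "wceclean-gbc",
        "version": 1,
        "parameters": _learned_parameters(model),
        "n_pixels": {"clean": model.clean.n_pixels, "contaminated": model.contaminated.n_pixels},
        "regularization_epsilon": model.regularization_epsilon,
        "fit_seed": model.fit_seed,
        "source_images": list(model.source_images),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_model(path: str | Path) -> GbcModel:
    """Load a model saved by :func:`save_model`; exact round-trip of all floats."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"{path}: not valid JSON") from exc
    if payload.get("format") != "wceclean-gbc":
        raise ModelFormatError(f"{path}: not a wceclean GBC model file")
    params = payload["parameters"]
    try:
        cms = {}
        for name in ("clean", "contaminated"):
            cms[name] = ClassModel(
                mean=np.array(params[f"{name}.mean"], dtype=float),
                covariance=np.array(params[f"{name}.covariance"], dtype=float).reshape(_D, _D),
                prior=float(params[f"{name}.prior"][0]),
                n_pixels=int(payload["n_pixels"][name]),
            )
        return GbcModel(
            clean=cms["clean"],
            contaminated=cms["contaminated"],
            regularization_epsilon=float(payload["regularization_epsilon"]),
            fit_seed=payload.get("fit_seed"),
            source_images=tuple(payload.get("source_images", ())),
        )
    except (KeyError, ValueError) as exc:
        raise ModelFormatError(f"{path}: malformed model file ({exc})") from exc
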