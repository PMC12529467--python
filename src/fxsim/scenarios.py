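"""Fire-exclusion (Fx) zone scenario construction.

Two neutral-landscape-model (NLM) generators control the spatial pattern of
Fx zones independent of ecology: a random map (dispersed) and a thresholded
fractional-Brownian-motion surface (clumped). Masks are then constrained to
mature, not-recently-burned stockable forest. An operational delineation
combines vulnerable-species density, fire-containment likelihood, and
developed areas into defensible patches. Patch statistics (component sizes,
edge density, spanning) quantify the configurations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from fxsim.grid import GridSpec
from fxsim.landscape import LandscapeState, OperationalInputs

FOUR_NEIGHBOR = ndimage.generate_binary_structure(2, 1)
EIGHT_NEIGHBOR = ndimage.generate_binary_structure(2, 2)


@dataclass
class PatchStats:
    """Connected-component summary of a binary Fx mask."""

    n_patches: int
    sizes: list[float]  # ha
    mean_size: float  # ha
    total_coverage: float  # fraction of stockable area
    edge_density: float  # boundary length per unit Fx area, 1/m
    largest_patch_spans: bool

    def __post_init__(self) -> None:
        if self.n_patches != len(self.sizes):
            raise ValueError("n_patches inconsistent with sizes")


@dataclass
class FxScenario:
    """A binary fire-exclusion mask with provenance and patch statistics."""

    mask: np.ndarray  # uint8, 1 = Fx
    kind: str  # "nlm" | "operational" | "reference"
    amount: float  # nominal fraction (0 for reference)
    configuration: str  # "dispersed" | "clumped" | "n/a"
    nlm_seed: int | None = None
    realized_coverage: float | None = None
    patch_stats: PatchStats | None = None
    label: str = field(default="")

    def __post_init__(self) -> None:
        if not self.label:
            if self.kind == "reference":
                self.label = "reference"
            elif self.kind == "operational":
                self.label = "operational"
            else:
                self.label = f"{self.configuration}-{int(round(self.amount * 100))}"


def reference_scenario(grid: GridSpec) -> FxScenario:
    """The no-exclusion reference: an all-zero mask."""
    return FxScenario(
        mask=np.zeros(grid.shape, dtype=np.uint8),
        kind="reference",
        amount=0.0,
        configuration="n/a",
        realized_coverage=0.0,
    )


def dispersed_nlm(stockable: np.ndarray, amount: float, seed: int) -> np.ndarray:
    """Random-map NLM: each stockable cell selected independently with
    probability ``amount``. Deterministic given ``seed``."""
    if not 0 < amount < 1:
        raise ValueError(f"amount must be in (0, 1), got {amount}")
    rng = np.random.default_rng(seed)
    draw = rng.random(stockable.shape) < amount
    return (draw & (stockable == 1)).astype(np.uint8)


def fbm_surface(shape: tuple[int, int], fractal_dim: float, seed: int) -> np.ndarray:
    """Fractional-Brownian-motion surface by spectral synthesis.

    The power spectrum falls off as f^-beta with beta = 2H + 2 where
    H = 2 - fractal_dim; small fractal dimensions give smooth, strongly
    autocorrelated surfaces. Synthesized on the full rectangle (callers clip
    to stockable afterwards).
    """
    if not 0 < fractal_dim < 2:
        raise ValueError(f"fractal_dim must be in (0, 2), got {fractal_dim}")
    hurst = 2.0 - fractal_dim
    beta = 2.0 * hurst + 2.0
    rng = np.random.default_rng(seed)
    nr, nc = shape
    fy = np.fft.fftfreq(nr)[:, None]
    fx = np.fft.fftfreq(nc)[None, :]
    f = np.sqrt(fy**2 + fx**2)
    with np.errstate(divide="ignore"):
        amplitude = np.where(f > 0, f ** (-beta / 2.0), 0.0)
    phase = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    surface = np.fft.ifft2(amplitude * phase).real
    if np.allclose(surface, surface.flat[0]):
        raise ValueError("degenerate constant fBm surface")
    return surface


def clumped_nlm(
    stockable: np.ndarray,
    amount: float,
    fractal_dim: float = 0.9,
    seed: int = 0,
) -> np.ndarray:
    """Clumped NLM: fBm surface binarized at the empirical quantile so that
    exactly ``ceil(amount * n_stockable)`` stockable cells are selected.

    Ties in surface values are broken by flattened cell index (stable sort),
    guaranteeing nominal coverage to within one cell's rounding.
    """
    if not 0 < amount < 1:
        raise ValueError(f"amount must be in (0, 1), got {amount}")
    surface = fbm_surface(stockable.shape, fractal_dim, seed)
    flat_idx = np.flatnonzero(stockable == 1)
    n_sel = int(np.ceil(amount * flat_idx.size))
    values = surface.ravel()[flat_idx]
    order = np.argsort(-values, kind="stable")  # top values; index breaks ties
    chosen = flat_idx[order[:n_sel]]
    mask = np.zeros(stockable.shape, dtype=np.uint8)
    mask.ravel()[chosen] = 1
    return mask


def constrain_placement(
    raw_mask: np.ndarray,
    state: LandscapeState,
    maturity_age: float = 60.0,
    recent_burn_horizon: float = 40.0,
) -> np.ndarray:
    """Restrict an NLM mask to mature, not-recently-burned stockable forest.

    Fx zones protect live seed sources, so cells that are non-stockable,
    younger than ``maturity_age``, or burned within ``recent_burn_horizon``
    years are dropped. Realized coverage can therefore fall below nominal.
    """
    if raw_mask.shape != state.grid.shape:
        raise ValueError(f"mask shape {raw_mask.shape} does not match landscape {state.grid.shape}")
    keep = (
        (raw_mask == 1)
        & (state.stockable == 1)
        & (state.stand_age >= maturity_age)
        & (state.time_since_fire >= recent_burn_horizon)
    )
    return keep.astype(np.uint8)


def nlm_scenario(
    state: LandscapeState,
    amount: float,
    configuration: str,
    nlm_seed: int,
    *,
    fractal_dim: float = 0.9,
    maturity_age: float = 60.0,
    recent_burn_horizon: float = 40.0,
    constrain: bool = True,
) -> FxScenario:
    """Build a constrained NLM Fx scenario (dispersed or clumped)."""
    if configuration == "dispersed":
        raw = dispersed_nlm(state.stockable, amount, nlm_seed)
    elif configuration == "clumped":
        raw = clumped_nlm(state.stockable, amount, fractal_dim, nlm_seed)
    else:
        raise ValueError(f"configuration must be 'dispersed' or 'clumped', got {configuration!r}")
    mask = constrain_placement(raw, state, maturity_age, recent_burn_horizon) if constrain else raw
    n_stock = int((state.stockable == 1).sum())
    scen = FxScenario(
        mask=mask,
        kind="nlm",
        amount=amount,
        configuration=configuration,
        nlm_seed=nlm_seed,
        realized_coverage=float(mask.sum()) / max(n_stock, 1),
    )
    scen.patch_stats = patch_statistics(mask, state.grid, neighbor_rule=8, stockable=state.stockable)
    return scen


def delineate_operational(
    inputs: OperationalInputs,
    state: LandscapeState,
    *,
    vuln_threshold: float = 50.0,
    containment_threshold: float = 0.20,
    min_patch_ha: float = 55.0,
    max_total: float = 0.30,
    maturity_age: float = 60.0,
) -> FxScenario:
    """Delineate operational Fx zones from firefighting considerations.

    Candidate cells hold at least ``vuln_threshold`` trees/ha of vulnerable
    species (fir, spruce, Douglas-fir), at least ``containment_threshold``
    fire-containment likelihood, and mature forest; developed areas are
    always included. Connected patches (8-neighbor) below ``min_patch_ha``
    are dropped; if total coverage exceeds ``max_total`` of stockable area,
    non-developed patches are dropped in ascending order of a priority score
    (mean vulnerable density x containment) until within budget.
    """
    if not 0 <= containment_threshold <= 1:
        raise ValueError("containment_threshold must be in [0, 1]")
    grid = state.grid
    mature = (state.stand_age >= maturity_age) & (state.stockable == 1)
    candidate = (
        (inputs.vulnerable_density >= vuln_threshold)
        & (inputs.containment_likelihood >= containment_threshold)
        & mature
    ) | (inputs.developed == 1)

    n_stock = max(int((state.stockable == 1).sum()), 1)
    if not np.any(candidate):
        warnings.warn("operational delineation found no candidate cells; returning empty scenario")
        scen = FxScenario(
            mask=np.zeros(grid.shape, dtype=np.uint8),
            kind="operational",
            amount=0.0,
            configuration="n/a",
            realized_coverage=0.0,
        )
        scen.patch_stats = patch_statistics(scen.mask, grid, 8, stockable=state.stockable)
        return scen

    labels, n_lab = ndimage.label(candidate, structure=EIGHT_NEIGHBOR)
    cell_ha = grid.cell_area_ha
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n_lab + 1))
    has_dev = ndimage.maximum(inputs.developed.astype(float), labels, index=np.arange(1, n_lab + 1)) > 0
    score = ndimage.mean(
        inputs.vulnerable_density * inputs.containment_likelihood, labels, index=np.arange(1, n_lab + 1)
    )

    keep = (sizes * cell_ha >= min_patch_ha) | has_dev
    # Enforce the coverage budget, protecting developed patches.
    order = np.argsort(score, kind="stable")  # lowest priority first
    total = float((sizes * keep).sum()) / n_stock
    for i in order:
        if total <= max_total:
            break
        if keep[i] and not has_dev[i] and total - sizes[i] / n_stock >= 0:
            keep[i] = False
            total -= sizes[i] / n_stock

    mask = np.zeros(grid.shape, dtype=np.uint8)
    kept_ids = np.flatnonzero(keep) + 1
    if kept_ids.size:
        mask[np.isin(labels, kept_ids)] = 1

    # Fallback when whole-patch drops cannot reach the budget (e.g. one
    # giant candidate patch): carve the mask along its weakest cells
    # (lowest vulnerable-density x containment), which splits it into
    # defensible sub-patches, then drop fragments below the minimum size.
    if mask.sum() / n_stock > max_total:
        cell_score = inputs.vulnerable_density * inputs.containment_likelihood
        trimmable = (mask == 1) & (inputs.developed == 0)
        budget = int(max_total * n_stock) - int((mask & (inputs.developed == 1)).sum())
        flat = np.flatnonzero(trimmable)
        ranked = flat[np.argsort(cell_score.ravel()[flat], kind="stable")]
        n_drop = max(flat.size - max(budget, 0), 0)
        mask.ravel()[ranked[:n_drop]] = 0
        labels2, n2 = ndimage.label(mask, structure=EIGHT_NEIGHBOR)
        if n2:
            sizes2 = ndimage.sum_labels(np.ones_like(labels2), labels2, index=np.arange(1, n2 + 1))
            dev2 = ndimage.maximum(inputs.developed.astype(float), labels2, index=np.arange(1, n2 + 1)) > 0
            small = (sizes2 * cell_ha < min_patch_ha) & ~dev2
            drop_ids = np.flatnonzero(small) + 1
            if drop_ids.size:
                mask[np.isin(labels2, drop_ids)] = 0
    scen = FxScenario(
        mask=mask,
        kind="operational",
        amount=max_total,
        configuration="n/a",
        realized_coverage=float(mask.sum()) / n_stock,
    )
    scen.patch_stats = patch_statistics(mask, grid, 8, stockable=state.stockable)
    return scen


def patch_statistics(
    mask: np.ndarray,
    grid: GridSpec,
    neighbor_rule: int = 8,
    stockable: np.ndarray | None = None,
) -> PatchStats:
    """Connected-component statistics of a binary mask.

    ``edge_density`` counts unit cell-boundary segments between mask and
    non-mask cells (the domain border counts as edge) and divides the
    resulting boundary length by the mask area. ``largest_patch_spans`` is
    true iff a single component touches both opposite borders (top-bottom or
    left-right). Coverage is relative to ``stockable`` (whole domain if not
    given).
    """
    if neighbor_rule not in (4, 8):
        raise ValueError("neighbor_rule must be 4 or 8")
    m = mask.astype(bool)
    structure = FOUR_NEIGHBOR if neighbor_rule == 4 else EIGHT_NEIGHBOR
    labels, n_patches = ndimage.label(m, structure=structure)
    cell_ha = grid.cell_area_ha
    if n_patches:
        counts = np.bincount(labels.ravel())[1:]
        sizes = (counts * cell_ha).tolist()
    else:
        sizes = []

    n_ref = int(stockable.sum()) if stockable is not None else grid.n_cells
    coverage = float(m.sum()) / max(n_ref, 1)

    # Edge segments: pairs of 4-adjacent cells with differing mask values,
    # plus mask cells on the domain border.
    pad = np.pad(m, 1, mode="constant", constant_values=False)
    n_edges = 0
    for axis in (0, 1):
        diff = np.diff(pad.astype(np.int8), axis=axis) != 0
        n_edges += int(diff.sum())
    edge_length = n_edges * grid.cell_size  # m
    fx_area = m.sum() * grid.cell_size**2  # m^2
    edge_density = edge_length / fx_area if fx_area > 0 else 0.0

    spans = False
    if n_patches:
        top = set(np.unique(labels[0])) - {0}
        bottom = set(np.unique(labels[-1])) - {0}
        left = set(np.unique(labels[:, 0])) - {0}
        right = set(np.unique(labels[:, -1])) - {0}
        spans = bool((top & bottom) or (left & right))

    return PatchStats(
        n_patches=int(n_patches),
        sizes=sizes,
        mean_size=float(np.mean(sizes)) if sizes else 0.0,
        total_coverage=coverage,
        edge_density=edge_density,
        largest_patch_spans=spans,
    )
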