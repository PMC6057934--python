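"""End-to-end convenience chain: intensity stack -> NetworkSummary."""

from __future__ import annotations

from typing import Optional

from scipy import ndimage

from . import element_descriptors as ed
from .gross_morphology import wrapped_hull
from .segmentation import BinaryMask, clean_mask, local_adaptive_threshold
from .spatial_graph import build_graph, distance_map, extract_centerline
from .stack_io import RunConfig, VoxelImage
from .summary import NetworkSummary


def segment_stack(image: VoxelImage, config: Optional[RunConfig] = None) -> BinaryMask:
    """Light Gaussian denoising, local adaptive threshold, component cleanup."""
    config = config or RunConfig()
    if any(s > 0 for s in config.presmooth_sigma_um):
        sigma_vox = [s / sp for s, sp in zip(config.presmooth_sigma_um, image.spacing)]
        smoothed = ndimage.gaussian_filter(
            image.intensities.astype(float), sigma=sigma_vox)
        image = VoxelImage(smoothed, image.spacing)
    mask = local_adaptive_threshold(image, config.window_radius_um,
                                    config.offset_fraction)
    return clean_mask(mask, config.min_component_voxels)


def quantify_mask(mask: BinaryMask, config: Optional[RunConfig] = None,
                  image: Optional[VoxelImage] = None, group: str = "",
                  source: str = "") -> NetworkSummary:
    """Wrapped hull + spatial graph + all 25 descriptors from a mask."""
    config = config or RunConfig()
    hull = wrapped_hull(mask)
    dmap = distance_map(mask)
    centerline = extract_centerline(mask, prune_length_um=config.prune_length_um,
                                    z_compression=config.thinning_z_compression)
    graph = build_graph(centerline, dmap, config, image=image)
    return ed.summarize_network(
        mask, hull, graph, group=group, source=source,
        curvature_stride_um=config.curvature_stride_um,
        tangent_offset_um=config.tangent_offset_um)


def quantify_stack(image: VoxelImage, config: Optional[RunConfig] = None,
                   group: str = "", source: str = "") -> NetworkSummary:
    """Full pipeline: segmentation, hull, graph extraction, descriptors."""
    config = config or RunConfig()
    mask = segment_stack(image, config)
    return quantify_mask(mask, config, image=image, group=group, source=source)
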