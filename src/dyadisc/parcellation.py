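"""Brain-region label registry.

Regions are opaque labels throughout the package: we emulate a whole-brain
parcellation consisting of a 200-parcel cortical scheme plus 14 bilateral
subcortical structures (214 regions in total), but carry no geometry.
"""

from __future__ import annotations

from dyadisc.exceptions import ConfigurationError

#: Seven bilateral subcortical structures -> 14 labels.
SUBCORTICAL_STRUCTURES = (
    "thalamus",
    "caudate",
    "putamen",
    "pallidum",
    "hippocampus",
    "amygdala",
    "accumbens",
)


def cortical_labels(n_cortical: int = 200) -> list[str]:
    """Opaque cortical parcel labels, split evenly between hemispheres."""
    if n_cortical < 2 or n_cortical % 2:
        raise ConfigurationError("n_cortical must be a positive even count")
    half = n_cortical // 2
    lh = [f"ctx_lh_{i:03d}" for i in range(1, half + 1)]
    rh = [f"ctx_rh_{i:03d}" for i in range(1, half + 1)]
    return lh + rh


def subcortical_labels() -> list[str]:
    """The 14 bilateral subcortical labels."""
    return [
        f"sub_{hemi}_{name}"
        for name in SUBCORTICAL_STRUCTURES
        for hemi in ("lh", "rh")
    ]


def build_region_registry(n_cortical: int = 200) -> list[str]:
    """Compose the full region registry: cortical parcels + 14 subcortical.

    With the default 200 cortical parcels this yields 214 unique labels.
    """
    labels = cortical_labels(n_cortical) + subcortical_labels()
    if len(set(labels)) != len(labels):
        raise ConfigurationError("region registry labels must be unique")
    return labels


def generic_region_labels(n_regions: int) -> list[str]:
    """Plain sequential labels (``r001`` ...) for reduced-scale simulations."""
    if n_regions < 1:
        raise ConfigurationError("n_regions must be >= 1")
    width = max(3, len(str(n_regions)))
    return [f"r{i:0{width}d}" for i in range(1, n_regions + 1)]
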