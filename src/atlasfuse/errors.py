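"""Exception types shared across modules."""


class AtlasFuseError(Exception):
    """Base class for all package errors."""


class OntologyError(AtlasFuseError):
    """Structural problem in a brain-region ontology (cycle, orphan, duplicate id)."""


class BoundsError(AtlasFuseError):
    """A voxel index or coordinate lies outside the reference grid."""


class StateError(AtlasFuseError):
    """Operation applied to a dataset in the wrong normalization state."""


class FilterError(AtlasFuseError):
    """Unknown metadata attribute or invalid filter specification."""


class AlignmentError(AtlasFuseError):
    """Inputs that must share an axis (regions, genes) do not."""


class EmptySelectionError(AtlasFuseError):
    """A VOI or filter selected no usable samples/voxels."""
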