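"""Exception types shared across the pipeline."""


class GridMismatchError(ValueError):
    """A spectrum/cube and a basis (or two cubes) do not share a wavelength grid."""


class FormatError(ValueError):
    """A CSV/TIFF artifact does not conform to the documented interface."""


class GeometryError(ValueError):
    """A phantom does not fit the requested field of view."""


class DegenerateReferenceError(ValueError):
    """White-light reference has non-positive reflectance in a normalization band."""


class TaskInfeasibleError(ValueError):
    """Fewer than two classes survive the balancing/exclusion rules."""


class DependencyError(RuntimeError):
    """A pipeline stage is missing an upstream artifact."""
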