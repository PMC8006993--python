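"""Exception types shared across the pipeline."""


class RootSpeckleError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(RootSpeckleError, ValueError):
    """Invalid or degenerate optical-geometry configuration."""


class InputError(RootSpeckleError, ValueError):
    """Invalid data passed to a pipeline operation."""


class ConfigError(RootSpeckleError, ValueError):
    """Malformed pipeline configuration (unknown keys, bad values)."""
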