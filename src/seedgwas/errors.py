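"""Exception types shared across the pipeline stages."""


class SeedGwasError(Exception):
    """Base class for all package-specific errors."""


class NoForeground(SeedGwasError):
    """Thresholding produced an empty foreground mask."""


class DegenerateShape(SeedGwasError):
    """A mask or polygon is too thin/small to carry geometry (e.g. a single
    pixel, or a polygon with zero area)."""


class MissingView(SeedGwasError):
    """A derived trait needs a view (dorsal/lateral/vertical) that was not
    measured."""


class UnbalancedDesign(SeedGwasError):
    """The genotype x environment x replicate layout has missing cells; the
    classical balanced ANOVA decomposition does not apply."""


class ConfigError(SeedGwasError):
    """A run configuration failed validation."""
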