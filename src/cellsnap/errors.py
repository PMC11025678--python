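"""Exception hierarchy."""


class CellSnapError(Exception):
    """Base class for all package errors."""


class ConfigError(CellSnapError):
    """Invalid or missing configuration."""


class FormatError(CellSnapError):
    """An input file violates the expected format."""


class ShapeMismatchError(CellSnapError):
    """Two grids that must share a shape do not."""


class EmptyCellError(CellSnapError):
    """A cell's rough volume contains no voxels above the medium RI."""


class EmptyTruthError(CellSnapError):
    """Pixel accuracy is undefined against an empty reference mask."""
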