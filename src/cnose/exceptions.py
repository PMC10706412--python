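"""Exception hierarchy for the cnose package."""


class CSAError(Exception):
    """Base class for sensor-array processing errors."""


class SegmentationError(CSAError):
    """Spot segmentation produced an unusable result (wrong count, bad registration)."""


class DataFormatError(CSAError):
    """An input file or table violates its declared format."""
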