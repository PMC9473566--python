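"""Shared test construction helpers."""

from nightshift.scene import AcquisitionGeometry


def geom(center=(60, 60), frame=(64, 64), **kw):
    """An acquisition with benign defaults, overridable per test."""
    defaults = dict(
        angle_deg=10.0,
        focal_mm=180.0,
        center_rowcol=center,
        timestamp=2013.0,
        exposure_s=0.25,
        iso=1600.0,
        frame_shape=frame,
        frame_id="t_000",
    )
    defaults.update(kw)
    return AcquisitionGeometry(**defaults)
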