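"""Shared programmatic fixtures for the test suite."""

import numpy as np

from nucoloc import ImageStack


def single_ellipsoid_stack(semiaxes_um=(2.0, 2.0, 6.0), intensity=200,
                           voxel_size=(0.21, 0.1, 0.1), pad=8):
    """A single uniform-intensity ellipsoid on zero background (DAPI only)."""
    az, ay, ax = (s / v for s, v in zip(semiaxes_um, voxel_size))
    shape = tuple(int(2 * a) + 2 * pad + 1 for a in (az, ay, ax))
    centre = np.array([(s - 1) / 2 for s in shape])
    zz, yy, xx = np.meshgrid(*map(np.arange, shape), indexing="ij")
    r = np.sqrt(((zz - centre[0]) / az) ** 2 + ((yy - centre[1]) / ay) ** 2
                + ((xx - centre[2]) / ax) ** 2)
    vox = np.zeros(shape + (1,), dtype=np.uint8)
    vox[r <= 1.0, 0] = intensity
    return ImageStack(voxels=vox, voxel_size=voxel_size, channel_roles={0: "DAPI"})
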