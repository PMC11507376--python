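"""Independent oracles used by the tests.

Everything here is written the slow, obvious way (triple loops, raw struct
packing) so it stays independent of the implementation paths it checks.
"""

import struct

import numpy as np


def brute_force_smooth(values: np.ndarray, window: int) -> np.ndarray:
    """Truncated-mean moving average by explicit triple loop over cells."""
    h = window // 2
    nx, ny, nz = values.shape
    out = np.empty_like(values, dtype=float)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                block = values[
                    max(i - h, 0) : min(i + h, nx - 1) + 1,
                    max(j - h, 0) : min(j + h, ny - 1) + 1,
                    max(k - h, 0) : min(k + h, nz - 1) + 1,
                ]
                out[i, j, k] = block.sum() / block.size
    return out


def nearest_index(point, origin, voxel):
    """Round-to-nearest index arithmetic, one axis at a time."""
    return tuple(int(round((point[a] - origin[a]) / voxel[a])) for a in range(3))


def write_raw_mrc(path, canonical_values, voxel, origin=None, axis_order=(1, 2, 3)):
    """Write a minimal MRC2014 file by raw struct packing.

    ``axis_order`` is (MAPC, MAPR, MAPS): which crystal axis (1=x, 2=y,
    3=z) the file's columns, rows and sections run along.  The data block
    is permuted accordingly, so a correct reader must undo the permutation
    to recover ``canonical_values``.
    """
    a = np.asarray(canonical_values, dtype=np.float32)
    perm = tuple(x - 1 for x in axis_order)  # crystal axis per (col, row, sec)
    dims = a.shape
    if sorted(axis_order) == [1, 2, 3]:
        f = np.transpose(a, (perm[2], perm[1], perm[0]))  # file array f[sec, row, col]
    else:
        f = a  # deliberately corrupt header: data layout does not matter
    header = bytearray(1024)

    def put_i32(word, value):
        struct.pack_into("<i", header, (word - 1) * 4, int(value))

    def put_f32(word, value):
        struct.pack_into("<f", header, (word - 1) * 4, float(value))

    valid = sorted(axis_order) == [1, 2, 3]
    put_i32(1, dims[perm[0]] if valid else dims[0])  # NX = n columns
    put_i32(2, dims[perm[1]] if valid else dims[1])  # NY = n rows
    put_i32(3, dims[perm[2]] if valid else dims[2])  # NZ = n sections
    put_i32(4, 2)  # MODE 2: float32
    for w in (5, 6, 7):
        put_i32(w, 0)
    for w, n in zip((8, 9, 10), dims):  # MX MY MZ: sampling along crystal axes
        put_i32(w, n)
    for w, n, v in zip((11, 12, 13), dims, voxel):
        put_f32(w, n * v)
    for w in (14, 15, 16):
        put_f32(w, 90.0)
    for w, x in zip((17, 18, 19), axis_order):
        put_i32(w, x)
    put_f32(20, float(a.min()))
    put_f32(21, float(a.max()))
    put_f32(22, float(a.mean()))
    put_i32(23, 1)  # ISPG P1
    put_i32(24, 0)  # NSYMBT
    if origin is not None:
        for w, v in zip((50, 51, 52), origin):
            put_f32(w, v)
    header[52 * 4 : 52 * 4 + 4] = b"MAP "
    header[53 * 4 : 53 * 4 + 4] = bytes([0x44, 0x44, 0x00, 0x00])  # little-endian stamp
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(np.ascontiguousarray(f).tobytes())


def random_rotation(rng):
    """Uniform random rotation matrix via quaternion normalization."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
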