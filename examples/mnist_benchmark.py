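"""Optional MNIST one-vs-all benchmark (opt-in; needs local IDX files).

This script never touches the network.  Download the four MNIST IDX files
yourself and point --data-dir at the directory containing:

    train-images-idx3-ubyte  train-labels-idx1-ubyte
    t10k-images-idx3-ubyte   t10k-labels-idx1-ubyte

(gzipped variants with .gz suffix are also accepted).  It trains a single
nMNSD to detect digit "1" versus the rest using 7x7 pixel-field latency
encoding (16 branches), then reports balanced test accuracy.  Expect a
few minutes on one core for the default subset sizes.
"""

import argparse
import gzip
import pathlib
import struct

import numpy as np

from nmnsd import (ImageEncodingParams, NMNSDStructure, STDPParams,
                   image_to_train, optimize_output_weights, predict_ova,
                   train_structure)


def _open(path: pathlib.Path):
    gz = path.with_name(path.name + ".gz")
    if path.exists():
        return open(path, "rb")
    if gz.exists():
        return gzip.open(gz, "rb")
    raise FileNotFoundError(f"{path} (or {gz.name}) not found")


def read_idx(path: pathlib.Path) -> np.ndarray:
    """Minimal IDX reader (big-endian magic + dims + uint8 payload)."""
    with _open(path) as fh:
        magic = struct.unpack(">I", fh.read(4))[0]
        ndim = magic & 0xFF
        dims = struct.unpack(">" + "I" * ndim, fh.read(4 * ndim))
        return np.frombuffer(fh.read(), dtype=np.uint8).reshape(dims)


def balanced_subset(images, labels, digit, per_class, rng):
    pos = np.flatnonzero(labels == digit)
    neg = np.flatnonzero(labels != digit)
    pos = rng.choice(pos, min(per_class, pos.size), replace=False)
    neg = rng.choice(neg, pos.size, replace=False)
    idx = np.concatenate([pos, neg])
    return images[idx], labels[idx] == digit


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", required=True)
    ap.add_argument("--digit", type=int, default=1)
    ap.add_argument("--n-train", type=int, default=1000,
                    help="positive training images (matched negatives)")
    ap.add_argument("--n-test", type=int, default=500)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    d = pathlib.Path(args.data_dir)
    rng = np.random.default_rng(args.seed)
    tr_img = read_idx(d / "train-images-idx3-ubyte")
    tr_lab = read_idx(d / "train-labels-idx1-ubyte")
    te_img = read_idx(d / "t10k-images-idx3-ubyte")
    te_lab = read_idx(d / "t10k-labels-idx1-ubyte")

    enc = ImageEncodingParams(field_size=7)
    Xtr, ytr = balanced_subset(tr_img, tr_lab, args.digit, args.n_train,
                               rng)
    Xte, yte = balanced_subset(te_img, te_lab, args.digit, args.n_test,
                               rng)
    print(f"digit {args.digit}: {ytr.sum()}+{(~ytr).sum()} train, "
          f"{yte.sum()}+{(~yte).sum()} test, 16 branches")

    s = NMNSDStructure.default(16, Ld=0.01)
    pos_trains = [image_to_train(im.astype(float), enc)
                  for im, y in zip(Xtr, ytr) if y]
    trained, _ = train_structure(
        s, pos_trains, STDPParams(A_plus=0.005, A_minus=-0.005),
        epochs=3, shuffle=True, seed=args.seed, average=True)

    val = [(image_to_train(im.astype(float), enc), bool(y))
           for im, y in zip(Xtr[:400], ytr[:400])]
    trained = optimize_output_weights(trained, val, maxiter=150)

    correct = sum(
        predict_ova(trained, image_to_train(im.astype(float), enc)).positive
        == bool(y) for im, y in zip(Xte, yte))
    print(f"balanced test accuracy: {correct / len(yte):.3f}")


if __name__ == "__main__":
    main()
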