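"""Minimal reverse-mode tensor autodiff.

Backward passes are themselves built from :class:`Tensor` operations, so
gradients are differentiable graphs: ``grad(grad(...))`` works.  This is what
the WGAN-GP gradient penalty needs -- the norm of the critic's input gradient
is part of the critic loss and must be differentiated w.r.t. the critic
weights.  Only the operations used by the models in this package are
implemented; everything runs on float64 numpy arrays on a single thread, which
makes training bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

Array = np.ndarray


class Tensor:
    """A numpy array with a record of how it was computed.

    Parameters
    ----------
    data:
        Array content (copied to float64 on construction).
    requires_grad:
        Mark this tensor as a differentiation root (a parameter or an input
        whose gradient is wanted).  Derived tensors inherit the flag from
        their parents.
    """

    __slots__ = ("data", "requires_grad", "_parents", "_vjps", "grad")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _vjps: tuple[Callable[["Tensor"], "Tensor"], ...] = (),
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents if self.requires_grad else ()
        self._vjps = _vjps if self.requires_grad else ()
        self.grad: "Tensor | None" = None

    # -- conveniences -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- operator sugar ---------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return neg(self)

    def __sub__(self, other):
        return add(self, neg(as_tensor(other)))

    def __rsub__(self, other):
        return add(as_tensor(other), neg(self))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(as_tensor(other), self)

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    @property
    def T(self):
        return transpose(self)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# broadcasting helper: reduce a gradient back to the shape of its source
# ---------------------------------------------------------------------------

def _unbroadcast(g: Tensor, shape: tuple[int, ...]) -> Tensor:
    while g.data.ndim > len(shape):
        g = tsum(g, axis=0)
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.data.shape[i] != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return Tensor(
        a.data + b.data,
        _parents=(a, b),
        _vjps=(
            lambda g: _unbroadcast(g, a.shape),
            lambda g: _unbroadcast(g, b.shape),
        ),
    )


def neg(a) -> Tensor:
    a = as_tensor(a)
    return Tensor(-a.data, _parents=(a,), _vjps=(lambda g: neg(g),))


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return Tensor(
        a.data * b.data,
        _parents=(a, b),
        _vjps=(
            lambda g: _unbroadcast(mul(g, b), a.shape),
            lambda g: _unbroadcast(mul(g, a), b.shape),
        ),
    )


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return Tensor(
        a.data / b.data,
        _parents=(a, b),
        _vjps=(
            lambda g: _unbroadcast(div(g, b), a.shape),
            lambda g: _unbroadcast(neg(div(mul(g, a), mul(b, b))), b.shape),
        ),
    )


def power(a, p: float) -> Tensor:
    a = as_tensor(a)
    p = float(p)
    return Tensor(
        a.data**p,
        _parents=(a,),
        _vjps=(lambda g: mul(g, mul(p, power(a, p - 1.0))),),
    )


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return Tensor(
        a.data @ b.data,
        _parents=(a, b),
        _vjps=(
            lambda g: matmul(g, transpose(b)),
            lambda g: matmul(transpose(a), g),
        ),
    )


def transpose(a) -> Tensor:
    a = as_tensor(a)
    return Tensor(a.data.T, _parents=(a,), _vjps=(lambda g: transpose(g),))


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    old = a.shape
    return Tensor(
        a.data.reshape(shape), _parents=(a,), _vjps=(lambda g: reshape(g, old),)
    )


def broadcast_to(a, shape) -> Tensor:
    a = as_tensor(a)
    old = a.shape
    return Tensor(
        np.broadcast_to(a.data, shape).copy(),
        _parents=(a,),
        _vjps=(lambda g: _unbroadcast(g, old),),
    )


def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    in_shape = a.shape

    if axis is None:
        axes = tuple(range(a.ndim))
    elif isinstance(axis, int):
        axes = (axis % a.ndim,)
    else:
        axes = tuple(ax % a.ndim for ax in axis)

    def vjp(g: Tensor) -> Tensor:
        if not keepdims:
            kshape = tuple(
                1 if i in axes else s for i, s in enumerate(in_shape)
            )
            g = reshape(g, kshape)
        return broadcast_to(g, in_shape)

    return Tensor(a.data.sum(axis=axis, keepdims=keepdims), _parents=(a,), _vjps=(vjp,))


def tmean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        n = a.data.size
    elif isinstance(axis, int):
        n = a.shape[axis]
    else:
        n = int(np.prod([a.shape[ax] for ax in axis]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def relu(a) -> Tensor:
    a = as_tensor(a)
    keep = Tensor((a.data > 0).astype(np.float64))  # constant; relu'' = 0 a.e.
    return Tensor(
        np.maximum(a.data, 0.0), _parents=(a,), _vjps=(lambda g: mul(g, keep),)
    )


def concat(parts: Sequence[Tensor], axis: int = 1) -> Tensor:
    parts = [as_tensor(p) for p in parts]
    sizes = [p.shape[axis] for p in parts]
    offsets = np.concatenate([[0], np.cumsum(sizes)]).astype(int)

    def make_vjp(i):
        sl = [slice(None)] * parts[i].ndim
        sl[axis] = slice(offsets[i], offsets[i + 1])
        sl = tuple(sl)
        return lambda g: getitem(g, sl)

    return Tensor(
        np.concatenate([p.data for p in parts], axis=axis),
        _parents=tuple(parts),
        _vjps=tuple(make_vjp(i) for i in range(len(parts))),
    )


def getitem(a, idx) -> Tensor:
    a = as_tensor(a)
    shape = a.shape

    def vjp(g: Tensor) -> Tensor:
        return scatter(g, idx, shape)

    return Tensor(a.data[idx], _parents=(a,), _vjps=(vjp,))


def scatter(g, idx, shape) -> Tensor:
    """Place ``g`` into a zero array of ``shape`` at ``idx`` (adjoint of getitem)."""
    g = as_tensor(g)

    def vjp(gg: Tensor) -> Tensor:
        return getitem(gg, idx)

    out = np.zeros(shape, dtype=np.float64)
    np.add.at(out, idx, g.data)
    return Tensor(out, _parents=(g,), _vjps=(vjp,))


def take_columns(a, cols) -> Tensor:
    """Select columns of a 2-D tensor by integer index array."""
    cols = np.asarray(cols, dtype=int)
    return getitem(a, (slice(None), cols))


# ---------------------------------------------------------------------------
# backward
# ---------------------------------------------------------------------------

def _topo_order(root: Tensor) -> list[Tensor]:
    order: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(root, False)]
    while stack:
        node, expanded = stack.pop()
        if expanded:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if p.requires_grad and id(p) not in seen:
                stack.append((p, False))
    return order  # parents before children


def grad(
    output: Tensor,
    inputs: Sequence[Tensor],
    grad_output: Tensor | None = None,
) -> list[Tensor]:
    """Gradients of ``output`` w.r.t. each tensor in ``inputs``.

    The returned tensors are part of the computation graph, so they can be
    differentiated again (needed for the gradient penalty).
    """
    if grad_output is None:
        grad_output = Tensor(np.ones_like(output.data))
    wanted = {id(t) for t in inputs}
    gmap: dict[int, Tensor] = {id(output): grad_output}
    results: dict[int, Tensor] = {}
    for node in reversed(_topo_order(output)):
        g = gmap.pop(id(node), None)
        if g is None:
            continue
        if id(node) in wanted:
            results[id(node)] = g
        for p, vjp in zip(node._parents, node._vjps):
            if not p.requires_grad:
                continue
            pg = vjp(g)
            acc = gmap.get(id(p))
            gmap[id(p)] = pg if acc is None else add(acc, pg)
    zero = lambda t: Tensor(np.zeros_like(t.data))
    return [results.get(id(t), zero(t)) for t in inputs]


def backward(loss: Tensor, params: Sequence[Tensor]) -> None:
    """Populate ``p.grad`` for each parameter (overwrites previous grads)."""
    for p, g in zip(params, grad(loss, params)):
        p.grad = g
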