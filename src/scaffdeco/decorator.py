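"""The generative core: a scaffold-decorator sequence model.

A bidirectional gated recurrent (LSTM) encoder reads the tokenized scaffold
in both directions and sums the direction-wise hidden states; a unidirectional
LSTM decoder, initialized from the summed final encoder state, emits the
decoration token by token, attending over all encoder positions with global
(Luong-style dot-product) attention at every step.  Training minimizes mean
per-token cross-entropy of the decoration given the scaffold, with Adam.

Two presets are provided: a desk-scale configuration (embedding 32, hidden
64, one encoder layer per direction, two decoder layers) that trains in
minutes on a CPU, and a larger ``paper_scale`` preset (hidden 256, two
encoder and two decoder layers).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from ._autograd import (
    Adam, Tensor, concat_last, cross_entropy, embedding, parameter,
    softmax_last, stack_axis1,
)
from .fragmentation import PairLibrary, ScaffoldDecorationPair, attach
from .smiles import ATTACHMENT, Vocabulary, build_vocab, dedup_key, tokenize

NEG = -1e9


@dataclass
class DecoratorConfig:
    embedding_size: int = 32
    hidden_size: int = 64
    encoder_layers: int = 1  # per direction
    decoder_layers: int = 2
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 300
    temperature: float = 1.0
    seed: int = 0
    max_decode_length: int = 100
    max_length: int = 120
    direction: str = "ltr"  # decoration reading direction

    def __post_init__(self):
        if min(self.embedding_size, self.hidden_size, self.encoder_layers,
               self.decoder_layers, self.batch_size, self.epochs) < 1:
            raise ValueError("all sizes must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")

    @classmethod
    def paper_scale(cls, **overrides) -> "DecoratorConfig":
        """Larger preset in the spirit of the published four-hidden-layer
        model; no exact parameter-count guarantee."""
        base = dict(embedding_size=64, hidden_size=256, encoder_layers=2, decoder_layers=2)
        base.update(overrides)
        return cls(**base)


@dataclass
class TrainingLog:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    token_accuracy: list[float] = field(default_factory=list)


@dataclass
class GenerationReport:
    """Attrition bookkeeping for a sampling run; the fractions are relative
    to ``n_sampled`` and satisfy n_novel ≤ n_unique ≤ n_valid ≤ n_sampled."""

    n_sampled: int
    n_valid: int
    n_unique: int
    n_novel: int
    n_mw_pass: int

    def __post_init__(self):
        if not (self.n_novel <= self.n_unique <= self.n_valid <= self.n_sampled):
            raise ValueError("inconsistent attrition counts")

    @property
    def validity(self) -> float:
        return self.n_valid / self.n_sampled if self.n_sampled else 0.0

    @property
    def uniqueness(self) -> float:
        return self.n_unique / self.n_valid if self.n_valid else 0.0

    @property
    def novelty(self) -> float:
        return self.n_novel / self.n_unique if self.n_unique else 0.0


def _lstm_step(x: Tensor, h: Tensor, c: Tensor, Wx: Tensor, Wh: Tensor, b: Tensor,
               hidden: int) -> tuple[Tensor, Tensor]:
    z = x @ Wx + h @ Wh + b
    i = z.slice_last(0, hidden).sigmoid()
    f = z.slice_last(hidden, 2 * hidden).sigmoid()
    g = z.slice_last(2 * hidden, 3 * hidden).tanh()
    o = z.slice_last(3 * hidden, 4 * hidden).sigmoid()
    c_new = f * c + i * g
    return o * c_new.tanh(), c_new


def _masked_carry(new: Tensor, old: Tensor, mask_col: np.ndarray) -> Tensor:
    """Keep the previous state at padded positions (mask 0)."""
    return new * mask_col + old * (1.0 - mask_col)


class ScaffoldDecorator:
    """Scaffold → decoration sequence model (fit / evaluate / sample)."""

    def __init__(self, pair_library: PairLibrary | list[ScaffoldDecorationPair],
                 config: DecoratorConfig | None = None,
                 vocabulary: Vocabulary | None = None):
        if isinstance(pair_library, PairLibrary):
            self.library = pair_library
        else:
            pairs = list(pair_library)
            self.library = PairLibrary(pairs, train=list(range(len(pairs))))
        self.config = config or DecoratorConfig()
        if not self.library.train:
            raise ValueError("empty training split")
        corpus = [p.scaffold_smiles for p in self.library.pairs] + [
            p.decoration_smiles for p in self.library.pairs]
        self.vocab = vocabulary or build_vocab(corpus)
        self._dropped_long = 0
        self.params: dict[str, Tensor] = {}
        self._init_params()
        self.training_keys: set[str] = set()

    # ------------------------------------------------------------ params
    def _init_params(self):
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        V, E, H = len(self.vocab), cfg.embedding_size, cfg.hidden_size
        p = self.params
        p["emb"] = parameter((V, E), rng)
        for layer in range(cfg.encoder_layers):
            in_dim = E if layer == 0 else H
            for d in ("f", "b"):
                p[f"enc{layer}{d}_Wx"] = parameter((in_dim, 4 * H), rng)
                p[f"enc{layer}{d}_Wh"] = parameter((H, 4 * H), rng)
                p[f"enc{layer}{d}_b"] = Tensor(np.zeros(4 * H), requires_grad=True)
        for layer in range(cfg.decoder_layers):
            in_dim = E if layer == 0 else H
            p[f"dec{layer}_Wx"] = parameter((in_dim, 4 * H), rng)
            p[f"dec{layer}_Wh"] = parameter((H, 4 * H), rng)
            p[f"dec{layer}_b"] = Tensor(np.zeros(4 * H), requires_grad=True)
        p["att_Wc"] = parameter((2 * H, H), rng)
        p["out_Wv"] = parameter((H, V), rng)
        p["out_bv"] = Tensor(np.zeros(V), requires_grad=True)

    @property
    def n_parameters(self) -> int:
        return sum(t.data.size for t in self.params.values())

    # ---------------------------------------------------------- encoding
    def _encode_batch(self, pairs: list[ScaffoldDecorationPair]):
        """Pad-encode scaffolds and decorations; drops pairs whose encoded
        length exceeds config.max_length (counted in ``_dropped_long``)."""
        cfg, vocab = self.config, self.vocab
        src, tgt = [], []
        for pr in pairs:
            try:
                s = vocab.encode(pr.scaffold_smiles, "ltr", cfg.max_length)
                d = vocab.encode(pr.decoration_smiles, cfg.direction, cfg.max_length)
            except ValueError:
                self._dropped_long += 1
                continue
            src.append(s)
            tgt.append(d)
        if not src:
            raise ValueError("no encodable pairs in batch")
        Ls = max(len(s) for s in src)
        Lt = max(len(t) for t in tgt)
        pad = vocab.pad
        S = np.full((len(src), Ls), pad, int)
        T = np.full((len(tgt), Lt), pad, int)
        for i, s in enumerate(src):
            S[i, : len(s)] = s
        for i, t in enumerate(tgt):
            T[i, : len(t)] = t
        return S, T

    def _run_encoder(self, S: np.ndarray):
        """Returns (enc_states (B,Ts,H) Tensor, summary h, summary c,
        attention additive mask (B,Ts))."""
        cfg, p = self.config, self.params
        B, Ts = S.shape
        H = cfg.hidden_size
        valid = (S != self.vocab.pad).astype(float)  # (B, Ts)
        inputs = [embedding(p["emb"], S[:, t]) for t in range(Ts)]
        summary_h = summary_c = None
        for layer in range(cfg.encoder_layers):
            outs_f, outs_b = [None] * Ts, [None] * Ts
            finals = {}
            for d, order in (("f", range(Ts)), ("b", range(Ts - 1, -1, -1))):
                Wx, Wh, b = (p[f"enc{layer}{d}_Wx"], p[f"enc{layer}{d}_Wh"], p[f"enc{layer}{d}_b"])
                h = Tensor(np.zeros((B, H)))
                c = Tensor(np.zeros((B, H)))
                for t in order:
                    m = valid[:, t][:, None]
                    h_new, c_new = _lstm_step(inputs[t], h, c, Wx, Wh, b, H)
                    h = _masked_carry(h_new, h, m)
                    c = _masked_carry(c_new, c, m)
                    (outs_f if d == "f" else outs_b)[t] = h
                finals[d] = (h, c)
            summed = [outs_f[t] + outs_b[t] for t in range(Ts)]
            summary_h = finals["f"][0] + finals["b"][0]
            summary_c = finals["f"][1] + finals["b"][1]
            inputs = summed
        enc_states = stack_axis1(inputs)  # (B, Ts, H)
        att_mask = np.where(valid > 0, 0.0, NEG)  # (B, Ts)
        return enc_states, summary_h, summary_c, att_mask

    def _decoder_logits(self, enc_states, summary_h, summary_c, att_mask,
                        T_in: np.ndarray):
        """Teacher-forced decoder: logits for each target position."""
        cfg, p = self.config, self.params
        B, Lt = T_in.shape
        H = cfg.hidden_size
        hs = [summary_h for _ in range(cfg.decoder_layers)]
        cs = [summary_c for _ in range(cfg.decoder_layers)]
        step_logits = []
        for t in range(Lt):
            x = embedding(p["emb"], T_in[:, t])
            for layer in range(cfg.decoder_layers):
                h_new, c_new = _lstm_step(
                    x, hs[layer], cs[layer],
                    p[f"dec{layer}_Wx"], p[f"dec{layer}_Wh"], p[f"dec{layer}_b"], H)
                hs[layer], cs[layer] = h_new, c_new
                x = h_new
            top = hs[-1]
            scores = (enc_states @ top.reshape(B, H, 1)).reshape(B, -1)
            alpha = softmax_last(scores, att_mask)
            context = (alpha.reshape(B, 1, -1) @ enc_states).reshape(B, H)
            h_tilde = (concat_last([context, top]) @ p["att_Wc"]).tanh()
            step_logits.append(h_tilde @ p["out_Wv"] + p["out_bv"])
        return step_logits

    def _batch_loss(self, pairs: list[ScaffoldDecorationPair]):
        """(loss Tensor, token count, per-token mean, accuracy) for a batch."""
        S, T = self._encode_batch(pairs)
        enc_states, sh, sc, att_mask = self._run_encoder(S)
        T_in, T_out = T[:, :-1], T[:, 1:]
        weights = (T_out != self.vocab.pad).astype(float)
        step_logits = self._decoder_logits(enc_states, sh, sc, att_mask, T_in)
        logits = stack_axis1(step_logits)  # (B, Lt-1, V)
        V = len(self.vocab)
        flat = logits.reshape(-1, V)
        loss_sum, total_w = cross_entropy(flat, T_out.reshape(-1), weights.reshape(-1))
        pred = flat.data.argmax(-1)
        correct = float(((pred == T_out.reshape(-1)) * weights.reshape(-1)).sum())
        return loss_sum, total_w, loss_sum.data.item() / total_w, correct / total_w

    # ---------------------------------------------------------------- fit
    def fit(self, callback=None) -> TrainingLog:
        """Train on the library's train split; per-epoch validation on the
        validation split when present.  Deterministic for a fixed seed."""
        cfg = self.config
        train_pairs = self.library.split("train")
        val_pairs = self.library.split("validation")
        opt = Adam(self.params, lr=cfg.learning_rate)
        shuffler = np.random.default_rng(cfg.seed + 1)
        log = TrainingLog()
        for epoch in range(cfg.epochs):
            order = shuffler.permutation(len(train_pairs))
            epoch_loss, epoch_tokens = 0.0, 0.0
            for start in range(0, len(order), cfg.batch_size):
                batch = [train_pairs[i] for i in order[start:start + cfg.batch_size]]
                opt.zero_grad()
                loss_sum, total_w, _, _ = self._batch_loss(batch)
                # mean-per-token objective: scale gradient by 1/total_w
                loss_sum.grad = None
                loss_sum.backward()
                for t in self.params.values():
                    if t.grad is not None:
                        t.grad /= total_w
                opt.step()
                epoch_loss += loss_sum.data.item()
                epoch_tokens += total_w
            log.train_loss.append(epoch_loss / epoch_tokens)
            if val_pairs:
                vloss, vacc = self.evaluate(val_pairs)
                log.val_loss.append(vloss)
                log.token_accuracy.append(vacc)
            if callback is not None:
                callback(epoch, log)
        self.training_keys = self._collect_training_keys()
        return log

    def _collect_training_keys(self) -> set[str]:
        keys = set()
        for pr in self.library.split("train"):
            try:
                keys.add(dedup_key(attach(pr.scaffold_smiles, pr.decoration_smiles)))
            except ValueError:
                continue
        return keys

    def evaluate(self, split) -> tuple[float, float]:
        """Teacher-forced mean per-token loss and exact-token accuracy on a
        split name ('train'/'validation'/'test') or a list of pairs."""
        pairs = self.library.split(split) if isinstance(split, str) else list(split)
        if not pairs:
            raise ValueError("empty split")
        total_loss = total_w = total_correct = 0.0
        for start in range(0, len(pairs), self.config.batch_size):
            batch = pairs[start:start + self.config.batch_size]
            loss_sum, w, _, acc = self._batch_loss(batch)
            total_loss += loss_sum.data.item()
            total_w += w
            total_correct += acc * w
        return total_loss / total_w, total_correct / total_w

    # ------------------------------------------------------------- sample
    def sample_decorations(self, scaffold: str, n: int,
                           temperature: float | None = None,
                           seed: int = 0, greedy: bool = False) -> list[str]:
        """Draw ``n`` decoration SMILES for one scaffold.

        Tokens are sampled from the temperature-scaled decoder distribution
        until END or ``max_decode_length``; PAD/START/UNK are masked out.
        ``greedy=True`` takes the argmax instead (the temperature → 0 limit).
        """
        n_attach = sum(1 for t in tokenize(scaffold) if t in (ATTACHMENT, "*"))
        if n_attach != 1:
            raise ValueError("scaffold must contain exactly one attachment token")
        if n == 0:
            return []
        cfg, vocab, p = self.config, self.vocab, self.params
        temperature = cfg.temperature if temperature is None else temperature
        rng = np.random.default_rng(seed)
        H = cfg.hidden_size
        S = np.array([vocab.encode(scaffold, "ltr", cfg.max_length)] * n)
        enc_states, sh, sc, att_mask = self._run_encoder(S)
        hs = [sh.data.copy() for _ in range(cfg.decoder_layers)]
        cs = [sc.data.copy() for _ in range(cfg.decoder_layers)]
        tokens = np.full(n, vocab.start, int)
        done = np.zeros(n, bool)
        out_tokens = [[] for _ in range(n)]
        forbidden = [vocab.pad, vocab.start, vocab.unk]
        enc = enc_states.data
        for _ in range(cfg.max_decode_length):
            x = p["emb"].data[tokens]
            for layer in range(cfg.decoder_layers):
                z = x @ p[f"dec{layer}_Wx"].data + hs[layer] @ p[f"dec{layer}_Wh"].data + p[f"dec{layer}_b"].data
                i = 1 / (1 + np.exp(-z[:, :H]))
                f = 1 / (1 + np.exp(-z[:, H:2 * H]))
                g = np.tanh(z[:, 2 * H:3 * H])
                o = 1 / (1 + np.exp(-z[:, 3 * H:]))
                cs[layer] = f * cs[layer] + i * g
                hs[layer] = o * np.tanh(cs[layer])
                x = hs[layer]
            top = hs[-1]
            scores = np.einsum("bth,bh->bt", enc, top) + att_mask
            alpha = np.exp(scores - scores.max(-1, keepdims=True))
            alpha /= alpha.sum(-1, keepdims=True)
            context = np.einsum("bt,bth->bh", alpha, enc)
            h_tilde = np.tanh(np.concatenate([context, top], -1) @ p["att_Wc"].data)
            logits = h_tilde @ p["out_Wv"].data + p["out_bv"].data
            logits[:, forbidden] = NEG
            if greedy:
                nxt = logits.argmax(-1)
            else:
                z = logits / temperature
                z -= z.max(-1, keepdims=True)
                prob = np.exp(z)
                prob /= prob.sum(-1, keepdims=True)
                u = rng.random((n, 1))
                nxt = (prob.cumsum(-1) < u).sum(-1)
            for b in range(n):
                if done[b]:
                    continue
                if nxt[b] == vocab.end:
                    done[b] = True
                else:
                    out_tokens[b].append(int(nxt[b]))
            tokens = np.where(done, vocab.end, nxt)
            if done.all():
                break
        return [
            vocab.decode([vocab.start] + toks + [vocab.end], self.config.direction)
            for toks in out_tokens
        ]

    def generate_library(self, scaffolds: list[str], n_per_scaffold: int,
                         mw_cutoff: float = 500.0, temperature: float | None = None,
                         seed: int = 0):
        """Sample decorations, attach, deduplicate and weight-filter.

        Returns (records, :class:`GenerationReport`).  Molecules with
        MW > ``mw_cutoff`` are dropped (the boundary is kept); deduplication
        is by InChI; novelty is relative to the attached training pairs.
        """
        from rdkit import Chem
        from rdkit.Chem import Descriptors
        from .synthetic import MoleculeRecord

        n_sampled = n_valid = 0
        seen: dict[str, str] = {}
        for si, scaffold in enumerate(scaffolds):
            decorations = self.sample_decorations(
                scaffold, n_per_scaffold, temperature, seed=seed + 7919 * si)
            for d in decorations:
                n_sampled += 1
                try:
                    smiles = attach(scaffold, d)
                except ValueError:
                    continue
                mol = Chem.MolFromSmiles(smiles)
                if mol is None:
                    continue
                n_valid += 1
                try:
                    key = dedup_key(smiles)
                except ValueError:
                    continue
                seen.setdefault(key, smiles)
        n_unique = len(seen)
        n_novel = len(set(seen) - self.training_keys)
        records = []
        for i, (key, smiles) in enumerate(sorted(seen.items())):
            mol = Chem.MolFromSmiles(smiles)
            if Descriptors.MolWt(mol) <= mw_cutoff:
                records.append(MoleculeRecord(f"GEN{i:05d}", smiles))
        report = GenerationReport(n_sampled, n_valid, n_unique, n_novel, len(records))
        return records, report

    # --------------------------------------------------------- checkpoint
    def save(self, path) -> None:
        arrays = {k: t.data for k, t in self.params.items()}
        meta = json.dumps({
            "config": asdict(self.config),
            "vocab": list(self.vocab.index_to_token),
            "training_keys": sorted(self.training_keys),
        })
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path, pair_library: PairLibrary | None = None) -> "ScaffoldDecorator":
        data = np.load(path)
        meta = json.loads(bytes(data["__meta__"]).decode())
        vocab = Vocabulary({t: i for i, t in enumerate(meta["vocab"])})
        config = DecoratorConfig(**meta["config"])
        library = pair_library or PairLibrary(
            [ScaffoldDecorationPair(f"c1ccccc1{ATTACHMENT}", f"C{ATTACHMENT}")], train=[0])
        model = cls(library, config, vocabulary=vocab)
        for k in model.params:
            model.params[k].data = data[k]
        model.training_keys = set(meta["training_keys"])
        return model


# ------------------------------------------------- spec-shaped module API

def train(pair_library: PairLibrary, config: DecoratorConfig | None = None
          ) -> tuple[ScaffoldDecorator, TrainingLog]:
    model = ScaffoldDecorator(pair_library, config)
    log = model.fit()
    return model, log


def sample_decorations(model: ScaffoldDecorator, scaffold: str, n: int,
                       temperature: float | None = None, seed: int = 0) -> list[str]:
    return model.sample_decorations(scaffold, n, temperature, seed)


def generate_library(model: ScaffoldDecorator, scaffolds: list[str],
                     n_per_scaffold: int, mw_cutoff: float = 500.0, seed: int = 0):
    return model.generate_library(scaffolds, n_per_scaffold, mw_cutoff, seed=seed)


def evaluate(model: ScaffoldDecorator, split) -> tuple[float, float]:
    return model.evaluate(split)
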