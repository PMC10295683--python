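"""Synthetic consultation-corpus generator.

Real diabetes Q&A corpora from online health communities are not freely
redistributable, so the pipeline is exercised on generated stand-ins: short
consultation-style documents assembled from clause templates whose slots are
filled with gazetteer surface strings, one gold span recorded per insertion.
Category inclusion probabilities default to the record frequencies observed
in such corpora (social and disease mentions in most records, mood in few);
gazetteers carry the characteristic high-frequency surfaces (fasting blood
glucose, metformin, hypertension, ...) plus fillers.  Documents are
template-based rather than natural language — sufficient for testing the
tagging pipeline, not a linguistic simulation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .corpus_io import AnnotatedDocument, EntitySpan
from .labels import CATEGORIES, DEFAULT_SCHEME, LabelScheme

# high-frequency surfaces of each category, with synthetic fillers
DEFAULT_GAZETTEERS: dict[str, list[str]] = {
    "check": ["血糖", "空腹血糖", "餐后血糖", "糖化血红蛋白", "体检", "血糖高",
              "糖耐量", "复查", "尿常规", "血脂检查"],
    "disease": ["糖尿病", "高血压", "高血糖", "二型糖尿病", "脂肪肝", "冠心病",
                "脑梗", "肥胖", "高血脂", "糖尿病并发症"],
    "drug": ["胰岛素", "二甲双胍", "阿卡波糖", "葡萄糖", "达格列净", "胰高血糖素",
             "格列美脲", "中药", "降压药", "维生素"],
    "life": ["控制血糖", "运动", "控制饮食", "睡眠不好", "停药", "减肥",
             "不吃药", "忌口", "熬夜", "散步"],
    "mood": ["担心", "疑惑", "害怕", "焦虑", "着急", "紧张", "疲惫", "生气",
             "不安", "烦躁"],
    "social": ["身高体重", "半年以上", "怀孕", "未怀孕", "半年内", "一月内",
               "一周内", "本人", "过敏", "父亲"],
    "symptom": ["口渴", "口苦口干", "头晕头昏", "多尿", "乏力", "消瘦", "恶心",
                "出汗", "心慌", "尿频"],
    "treat": ["手术", "化疗", "放疗", "药物治疗", "住院治疗", "减重", "中医",
              "支架", "微创", "免疫"],
}

# record frequencies (fraction of records mentioning the category)
DEFAULT_INCLUSION: dict[str, float] = {
    "check": 0.80, "disease": 0.8005, "drug": 0.564, "life": 0.2592,
    "mood": 0.0761, "social": 0.8968, "symptom": 0.364, "treat": 0.2208,
}

# clause templates per category; {} is the mention slot
DEFAULT_TEMPLATES: dict[str, list[str]] = {
    "check": ["昨天查了{}，", "医生让做{}，", "最近{}偏高，", "报告显示{}异常，"],
    "disease": ["确诊了{}，", "家里有{}史，", "会不会发展成{}，", "之前得过{}，"],
    "drug": ["一直在吃{}，", "医生开了{}，", "想停用{}，", "每天打{}，"],
    "life": ["平时坚持{}，", "医生建议{}，", "最近开始{}，"],
    "mood": ["心里很{}，", "整个人特别{}，"],
    "social": ["信息：{}，", "病程{}，", "情况是{}，"],
    "symptom": ["这几天总是{}，", "感觉有点{}，", "出现了{}症状，"],
    "treat": ["考虑做{}，", "已经接受{}，", "准备进行{}，"],
}

FILLERS = ["请问医生怎么办。", "需要注意什么。", "谢谢大夫。", "麻烦给点建议。",
           "这种情况严重吗。", "要不要去医院。"]

NOISE_ALPHABET = "的了吗呢啊吧嗯哦呀也都很还就要去看说问天人体好多少高低"


@dataclass
class Bookkeeping:
    """Exact generation counts, for closing the loop against
    :func:`ohcner.evaluation.corpus_statistics`."""

    total_records: int = 0
    records_with_mention: Counter = field(default_factory=Counter)
    mention_counts: Counter = field(default_factory=Counter)
    surface_counts: dict[str, Counter] = field(default_factory=dict)


@dataclass
class GeneratorConfig:
    n_documents: int = 200
    gazetteers: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_GAZETTEERS.items()})
    inclusion: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INCLUSION))
    templates: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_TEMPLATES.items()})
    max_mentions_per_category: int = 2
    max_doc_len: int = 128
    noise_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for cat, p in self.inclusion.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"inclusion probability for {cat} outside [0,1]")
            if p > 0 and not self.gazetteers.get(cat):
                raise ValueError(f"active category {cat} has an empty gazetteer")
            if p > 0 and not self.templates.get(cat):
                raise ValueError(f"active category {cat} has no templates")


def generate_corpus(config: GeneratorConfig | None = None,
                    scheme: LabelScheme = DEFAULT_SCHEME
                    ) -> tuple[list[AnnotatedDocument], Bookkeeping]:
    """Build a seed-deterministic annotated corpus plus exact bookkeeping."""
    config = config if config is not None else GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    books = Bookkeeping(total_records=config.n_documents,
                        surface_counts={c: Counter() for c in scheme.categories})
    docs: list[AnnotatedDocument] = []
    cats = [c for c in scheme.categories if config.inclusion.get(c, 0.0) > 0]
    for i in range(config.n_documents):
        parts: list[str] = []
        spans: list[EntitySpan] = []
        length = 0
        included = [c for c in cats if rng.random() < config.inclusion[c]]
        doc_cats: set[str] = set()
        for cat in included:
            n_mentions = int(rng.integers(1, config.max_mentions_per_category + 1))
            for _ in range(n_mentions):
                template = str(rng.choice(config.templates[cat]))
                surface = str(rng.choice(config.gazetteers[cat]))
                clause = template.format(surface)
                if length + len(clause) > config.max_doc_len - 8:
                    break
                slot = template.index("{}")
                spans.append(EntitySpan(length + slot,
                                        length + slot + len(surface), cat))
                parts.append(clause)
                length += len(clause)
                doc_cats.add(cat)
                books.mention_counts[cat] += 1
                books.surface_counts[cat][surface] += 1
        filler = str(rng.choice(FILLERS))
        if length + len(filler) <= config.max_doc_len:
            parts.append(filler)
        for cat in doc_cats:
            books.records_with_mention[cat] += 1
        doc = AnnotatedDocument(f"synth-{config.seed}-{i}", "".join(parts), spans)
        docs.append(doc.validate(scheme))
    if config.noise_rate > 0:
        docs = inject_noise(docs, config.noise_rate, seed=config.seed + 1)
    return docs, books


def inject_noise(docs: list[AnnotatedDocument], rate: float,
                 seed: int = 0) -> list[AnnotatedDocument]:
    """Substitute characters outside gold spans at the given rate.

    Emulates the colloquial typos of patient-written text while keeping
    every annotated surface exact, so span offsets stay valid.
    """
    if not (0.0 <= rate <= 1.0):
        raise ValueError("noise rate must lie in [0, 1]")
    if rate == 0.0:
        return docs
    rng = np.random.default_rng(seed)
    out = []
    for doc in docs:
        protected = np.zeros(len(doc.text), dtype=bool)
        for s in doc.spans:
            protected[s.start:s.end] = True
        chars = list(doc.text)
        for i, ch in enumerate(chars):
            if not protected[i] and rng.random() < rate:
                chars[i] = str(rng.choice(list(NOISE_ALPHABET)))
        out.append(AnnotatedDocument(doc.doc_id, "".join(chars), list(doc.spans)))
    return out
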