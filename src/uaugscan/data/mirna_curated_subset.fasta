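>hsa-let-7d MIMAT0000065 mature miRNA (curated subset)
AGAGGUAGUAGGUUGCAUAGUU
>mmu-let-7d MIMAT0000383 mature miRNA (curated subset)
AGAGGUAGUAGGUUGCAUAGUU
>hsa-miR-31 MIMAT0000089 mature miRNA (curated subset)
AGGCAAGAUGCUGGCAUAGCU
>mmu-miR-31 MIMAT0000538 mature miRNA (curated subset)
AGGCAAGAUGCUGGCAUAGCUG
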