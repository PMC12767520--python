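Write a summary based only on the context to summarize the functions of the query gene with about {total_words} words. Highlight the query gene and its interactions with genes in the interacting_genes list. If you cannot see any genes listed in the interacting genes in the context, it is fine not mentioning them. Don’t speculate! Make sure to cite the original context sources, which are provided at the start of each paragraph before “: “, using a format like this [PMID: 123456]. Don’t just list interacting genes if there is no information.
query_gene: {query_gene}
interacting_genes: {interacting_genes}
context: {context} 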