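The text in the abstract section is excerpts of scientific papers’ abstracts collected from PubMed and best matched with pathway text below. Write a summary of the abstract text with about {total_words} words to highlight the query_gene and its interaction with interacting_genes, so that Reactome curators can create reactions based on the original papers. The generated text should be based on the abstract text below only, providing evidence showing the possible functions of the query gene in the pathway, {pathway}. Don’t speculate and don’t mention interacting genes if you cannot see them in the abstract text. Don’t just list interacting genes if there is no information.
query_gene: {query_gene}
interacting_genes: {interacting_genes}
pathway_text: {pathway_text}
abstract: {abstract_text}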