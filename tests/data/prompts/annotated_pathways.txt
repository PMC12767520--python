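The gene below has been annotated in multiple pathways described in the context text below in Reactome. Write a summary having about {total_words} words with focus on the molecular functions of the gene in these pathways. Use the context text only for the summary and don’t speculate anything that is not in the text. Make sure to cite the pathway names in the format like this [Pathway_Name] for each sentence. The pathway names are provided in the context. Write a summary sentence at the end to summarize all results.
gene: {gene}
context: {annotated_pathways_text}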