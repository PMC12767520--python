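Extract functional relationships between the query gene specified below and other genes, proteins, or biological concepts from the following document. Output the relationships in the following format: {query_gene} - relationship_type -> other gene or protein or biological concept. If you can find the cellular component, tissue or cell type, or other experimental system related to the extracted relationships, make sure to list them.
query_gene: {query_gene}
document: {document}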