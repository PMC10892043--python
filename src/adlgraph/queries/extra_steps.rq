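PREFIX adl: <http://example.org/adl/ontology#>
PREFIX xsd: <http://www.w3.org/2001/XMLSchema#>

CONSTRUCT {
  ?problem a adl:ExtraSteps ;
           adl:isProblemOf ?patient ;
           adl:problem_date ?start ;
           adl:problem_rate ?steps .
}
WHERE {
  {
    SELECT ?activity_pk ?patient ?start (COUNT(DISTINCT ?event) AS ?steps)
    WHERE {
      ?activity a adl:Activity ;
                adl:activity_name ${activity_name} ;
                adl:activity_pk ?activity_pk ;
                adl:activity_start ?start ;
                adl:consistsOf ?event ;
                adl:refersToUser ?patient .
    }
    GROUP BY ?activity_pk ?patient ?start
  }
  FILTER( ?steps > ${extra_steps_threshold} )
  BIND( IRI(CONCAT("${resource_base}problem/extra-steps/",
                   ENCODE_FOR_URI(?activity_pk))) AS ?problem )
}
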